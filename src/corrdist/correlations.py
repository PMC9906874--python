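"""Correlation measures between expression profiles.

Three similarity measures are supported, all bounded in [-1, 1]:

* **Pearson correlation** -- covariance over the product of standard
  deviations; invariant under shifting and positive scaling of either
  profile.
* **Spearman correlation** -- Pearson correlation of the rank-transformed
  values (average ranks for ties); robust to monotone transforms.
* **Uncentered Pearson correlation** (cosine similarity) -- normalized dot
  product without mean-centering; invariant under positive scaling only.

A key identity used throughout the package: after a profile is shifted to
zero mean and scaled to unit Euclidean norm, the Pearson correlation of two
profiles is exactly the dot product of their normalized forms.  This reduces
correlation geometry to ordinary Euclidean geometry on the unit sphere and
is what makes sqrt(1 - |rho|) a metric (see :mod:`corrdist.distances`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateProfileError, ValidationError

__all__ = [
    "Profile",
    "CorrelationKind",
    "normalize_profile",
    "rank_transform",
    "pearson",
    "spearman",
    "uncentered",
    "correlation",
    "pairwise_correlation",
]

#: correlations are clamped into [-1, 1]; values beyond this slack are errors
CLAMP_TOL = 1e-12


class CorrelationKind(str, Enum):
    """Closed enumeration of the supported correlation measures."""

    PEARSON = "pearson"
    SPEARMAN = "spearman"
    UNCENTERED = "uncentered"


@dataclass(frozen=True)
class Profile:
    """A labeled expression profile: one item measured across n dimensions."""

    id: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValidationError(
                f"profile {self.id!r} must be a 1-D vector of length >= 2"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError(f"profile {self.id!r} contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


def _as_values(x, what: str = "profile") -> tuple[np.ndarray, str]:
    """Accept a Profile or an array-like; return (values, id-for-errors)."""
    if isinstance(x, Profile):
        return x.values, x.id
    values = np.asarray(x, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValidationError(f"{what} must be a 1-D vector of length >= 2")
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{what} contains non-finite values")
    return values, what


def _clamp(rho: float) -> float:
    if rho > 1.0 + CLAMP_TOL or rho < -1.0 - CLAMP_TOL:
        raise ValidationError(f"correlation {rho} outside [-1, 1] beyond tolerance")
    return float(min(1.0, max(-1.0, rho)))


def normalize_profile(p) -> np.ndarray:
    """Shift a profile to zero mean and scale it to unit Euclidean norm.

    The returned vector x~ satisfies sum(x~) = 0 and ||x~||_2 = 1, so that
    ``pearson(x, y) == normalize_profile(x) @ normalize_profile(y)``.

    Raises
    ------
    DegenerateProfileError
        If the profile is constant (zero variance), in which case no
        direction remains after centering.
    """
    values, item_id = _as_values(p)
    centered = values - values.mean()
    norm = np.linalg.norm(centered)
    if norm == 0.0:
        raise DegenerateProfileError(
            f"degenerate profile {item_id!r}: zero variance", item_id=item_id
        )
    return centered / norm


def rank_transform(p) -> np.ndarray:
    """Average ranks in 1..n; tied values share the mean of their positions."""
    values, _ = _as_values(p)
    return rankdata(values, method="average")


def _check_pair(x, y):
    xv, xid = _as_values(x, "x")
    yv, yid = _as_values(y, "y")
    if xv.size != yv.size:
        raise ValidationError(
            f"length mismatch: {xid!r} has {xv.size}, {yid!r} has {yv.size}"
        )
    return xv, yv


def pearson(x, y) -> float:
    """Pearson correlation of two equal-length, non-constant profiles.

    Computed as the dot product of the normalized (zero-mean, unit-norm)
    profiles, which is algebraically identical to the usual
    covariance-over-standard-deviations form.
    """
    _check_pair(x, y)
    return _clamp(float(np.dot(normalize_profile(x), normalize_profile(y))))


_pearson = pearson


def spearman(x, y) -> float:
    """Spearman correlation: Pearson on average-rank-transformed values."""
    xv, yv = _check_pair(x, y)
    return _pearson(rank_transform(xv), rank_transform(yv))


def uncentered(x, y) -> float:
    """Uncentered Pearson correlation (cosine similarity).

    ``sum(x_i * y_i) / (||x|| * ||y||)`` -- no mean-centering, so the
    measure is invariant under positive scaling but not under shifting.
    """
    xv, yv = _check_pair(x, y)
    nx, ny = np.linalg.norm(xv), np.linalg.norm(yv)
    if nx == 0.0 or ny == 0.0:
        bad = "x" if nx == 0.0 else "y"
        raise DegenerateProfileError(f"degenerate profile {bad!r}: zero norm")
    return _clamp(float(np.dot(xv, yv) / (nx * ny)))


def correlation(x, y, kind: CorrelationKind | str) -> float:
    """Dispatch to :func:`pearson`, :func:`spearman`, or :func:`uncentered`."""
    kind = CorrelationKind(kind)
    if kind is CorrelationKind.PEARSON:
        return _pearson(x, y)
    if kind is CorrelationKind.SPEARMAN:
        return spearman(x, y)
    return uncentered(x, y)


def pairwise_correlation(
    values: np.ndarray,
    kind: CorrelationKind | str,
    item_ids=None,
) -> np.ndarray:
    """All pairwise correlations between the rows of ``values``.

    Vectorized equivalent of calling :func:`correlation` on every row pair.
    Degenerate rows (zero variance for Pearson/Spearman, zero norm for the
    uncentered measure) raise :class:`DegenerateProfileError` naming the
    first offending item.
    """
    kind = CorrelationKind(kind)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 rows")
    if item_ids is None:
        item_ids = [str(i) for i in range(values.shape[0])]

    if kind is CorrelationKind.SPEARMAN:
        values = np.apply_along_axis(
            lambda r: rankdata(r, method="average"), 1, values
        )

    if kind is CorrelationKind.UNCENTERED:
        norms = np.linalg.norm(values, axis=1)
        bad = np.flatnonzero(norms == 0.0)
        if bad.size:
            raise DegenerateProfileError(
                f"degenerate profile {item_ids[bad[0]]!r}: zero norm",
                item_id=str(item_ids[bad[0]]),
            )
        unit = values / norms[:, None]
    else:
        centered = values - values.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        bad = np.flatnonzero(norms == 0.0)
        if bad.size:
            raise DegenerateProfileError(
                f"degenerate profile {item_ids[bad[0]]!r}: zero variance",
                item_id=str(item_ids[bad[0]]),
            )
        unit = centered / norms[:, None]

    rho = unit @ unit.T
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 1.0)
    return rho
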
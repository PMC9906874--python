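"""The correlation-distance family and the triangle-inequality auditor.

Given a correlation rho in [-1, 1], the family comprises

* ``d_a = 1 - |rho|`` -- the absolute correlation distance.  Treats strong
  positive and strong negative correlation as equally close, but is **not**
  a metric: the triangle inequality can fail.
* ``d_r = sqrt(1 - |rho|)`` -- the metric variant of ``d_a``.  A metric for
  Pearson, Spearman, and uncentered Pearson correlation, because on
  normalized profiles ``sqrt(2) * d_r = min(||X - Y||, ||X + Y||)``, i.e. the
  Euclidean distance to the nearer of Y and -Y.
* ``d_s = sqrt(1 - rho^2)`` -- metric alternative; note
  ``d_s = sqrt(d_a * (2 - d_a)) >= d_r`` with equality only at |rho| in {0,1}.
* ``d_o = sqrt((1 - rho) / 2)`` -- metric, but *signed*: at rho = -1 it
  returns 1 rather than 0, so anti-correlated profiles are maximally far.
* ``d_alpha = sqrt(1 - |rho|^alpha)`` -- one-parameter generalization with
  ``d_r`` as the alpha = 1 case.  Its metric status for alpha != 1 is not
  established here; audit it empirically.

``audit_triangle`` checks every ordered triple (i, j, k) of a distance
matrix for ``d(i,k) > d(i,j) + d(j,k) + tolerance`` and reports the
violations, so the metric claims above are executable rather than
aspirational.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .correlations import CorrelationKind, pairwise_correlation
from .errors import ValidationError

__all__ = [
    "DistanceKind",
    "DistanceMatrix",
    "MetricAuditReport",
    "transform",
    "distance_matrix",
    "min_norm_distance",
    "audit_triangle",
]

#: default slack separating true triangle violations from rounding noise
AUDIT_TOL = 1e-9

#: above this many items the auditor samples triples instead of enumerating
EXHAUSTIVE_LIMIT = 200

_NORM_TOL = 1e-9


class DistanceKind(str, Enum):
    D_A = "d_a"
    D_R = "d_r"
    D_S = "d_s"
    D_O = "d_o"
    D_ALPHA = "d_alpha"


def transform(rho, kind: DistanceKind | str, alpha: float | None = None):
    """Map a correlation (scalar or array) to a distance in [0, 1]."""
    kind = DistanceKind(kind)
    rho = np.asarray(rho, dtype=float)
    if np.any(rho > 1.0 + 1e-12) or np.any(rho < -1.0 - 1e-12):
        raise ValidationError("correlation outside [-1, 1]")
    rho = np.clip(rho, -1.0, 1.0)
    if kind is DistanceKind.D_A:
        out = 1.0 - np.abs(rho)
    elif kind is DistanceKind.D_R:
        out = np.sqrt(1.0 - np.abs(rho))
    elif kind is DistanceKind.D_S:
        out = np.sqrt(np.maximum(0.0, 1.0 - rho**2))
    elif kind is DistanceKind.D_O:
        out = np.sqrt((1.0 - rho) / 2.0)
    else:
        if alpha is None or alpha <= 0:
            raise ValidationError("d_alpha requires alpha > 0")
        out = np.sqrt(np.maximum(0.0, 1.0 - np.abs(rho) ** alpha))
    return float(out) if out.ndim == 0 else out


@dataclass
class DistanceMatrix:
    """A square symmetric distance matrix tagged with its provenance.

    ``values[i, j]`` is the distance between ``items[i]`` and ``items[j]``.
    Invariants (checked by :meth:`validate`): symmetry within 1e-12, zero
    diagonal, nonnegative entries, and entries <= 1 for the bounded kinds.
    """

    items: list[str]
    values: np.ndarray = field(repr=False)
    correlation_kind: CorrelationKind | None = None
    distance_kind: DistanceKind | None = None
    alpha: float | None = None

    def __post_init__(self):
        self.items = [str(i) for i in self.items]
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self):
        n = len(self.items)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} items"
            )
        if len(set(self.items)) != n:
            raise ValidationError("duplicate item identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite distance entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-12:
            raise ValidationError("matrix is not symmetric within 1e-12")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 0.0:
            raise ValidationError("diagonal is not zero")
        if self.values.min(initial=0.0) < 0.0:
            raise ValidationError("negative distance entries")
        bounded = {DistanceKind.D_A, DistanceKind.D_R, DistanceKind.D_S, DistanceKind.D_O}
        if self.distance_kind in bounded and self.values.max(initial=0.0) > 1.0 + 1e-12:
            raise ValidationError(f"{self.distance_kind.value} entries must be <= 1")

    @property
    def n(self) -> int:
        return len(self.items)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.items, columns=self.items)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def write(self, path):
        """Write as delimited text at full double precision (bit-exact round trip)."""
        self.to_dataframe().to_csv(path, float_format=lambda v: format(v, ".17g"))

    @classmethod
    def read(cls, path, correlation_kind=None, distance_kind=None, alpha=None):
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        df.index = df.index.map(str)
        df.columns = df.columns.map(str)
        if list(df.index) != list(df.columns):
            raise ValidationError("row and column identifiers differ")
        return cls(
            items=list(df.index),
            values=df.to_numpy(dtype=float),
            correlation_kind=CorrelationKind(correlation_kind) if correlation_kind else None,
            distance_kind=DistanceKind(distance_kind) if distance_kind else None,
            alpha=alpha,
        )


def distance_matrix(
    matrix,
    ckind: CorrelationKind | str = CorrelationKind.PEARSON,
    dkind: DistanceKind | str = DistanceKind.D_R,
    axis: str = "items",
    alpha: float | None = None,
) -> DistanceMatrix:
    """Pairwise distances between profiles of an expression matrix.

    Parameters
    ----------
    matrix
        A pandas DataFrame (items in rows, dimensions in columns) or a plain
        2-D array.
    axis
        ``"items"`` clusters the rows; ``"dimensions"`` transposes first, so
        the same call serves gene clustering and sample clustering.
    """
    if axis not in ("items", "dimensions"):
        raise ValidationError(f"unknown axis {axis!r}")
    if isinstance(matrix, pd.DataFrame):
        df = matrix if axis == "items" else matrix.T
        items = [str(i) for i in df.index]
        values = df.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        if axis == "dimensions":
            values = values.T
        items = [str(i) for i in range(values.shape[0])]
    if values.shape[0] < 2:
        raise ValidationError("need at least 2 items along the chosen axis")
    ckind, dkind = CorrelationKind(ckind), DistanceKind(dkind)
    rho = pairwise_correlation(values, ckind, item_ids=items)
    d = transform(rho, dkind, alpha=alpha)
    d = np.asarray(d)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # symmetrize away rounding asymmetry
    return DistanceMatrix(items, d, ckind, dkind, alpha)


def min_norm_distance(xn: np.ndarray, yn: np.ndarray) -> float:
    """min(||X - Y||, ||X + Y||) for normalized profiles.

    Equals ``sqrt(2 - 2|X . Y|)`` and therefore ``sqrt(2) * d_r``; serves as
    an independent Euclidean-geometry oracle for the d_r transform.
    """
    for name, v in (("x", np.asarray(xn, float)), ("y", np.asarray(yn, float))):
        if abs(v.sum()) > _NORM_TOL or abs((v**2).sum() - 1.0) > _NORM_TOL:
            raise ValidationError(f"{name} is not normalized (zero mean, unit norm)")
    xn, yn = np.asarray(xn, float), np.asarray(yn, float)
    return float(min(np.linalg.norm(xn - yn), np.linalg.norm(xn + yn)))


@dataclass
class MetricAuditReport:
    """Outcome of a triangle-inequality audit.

    ``violations`` holds unordered triples {i, j, k} reported in their
    maximizing arrangement (i, j, k) meaning d(i,k) > d(i,j) + d(j,k), with
    the positive slack d(i,k) - d(i,j) - d(j,k).
    """

    triples_checked: int
    violations: list[tuple[str, str, str, float]]
    max_slack: float
    mode: str
    tolerance: float
    seed: int | None = None
    distance_kind: DistanceKind | None = None
    alpha: float | None = None

    @property
    def n_violations(self) -> int:
        return len(self.violations)

    @property
    def metric_note(self) -> str | None:
        if self.distance_kind is DistanceKind.D_ALPHA and self.alpha != 1.0:
            return "metric status unverified for d_alpha with alpha != 1"
        return None

    def to_json(self) -> str:
        payload = {
            "triples_checked": self.triples_checked,
            "n_violations": self.n_violations,
            "max_slack": self.max_slack,
            "mode": self.mode,
            "tolerance": self.tolerance,
            "seed": self.seed,
            "distance_kind": self.distance_kind.value if self.distance_kind else None,
            "alpha": self.alpha,
            "violations": [
                {"i": i, "j": j, "k": k, "slack": s} for i, j, k, s in self.violations
            ],
        }
        if self.metric_note:
            payload["note"] = self.metric_note
        return json.dumps(payload, indent=2)


def audit_triangle(
    d: DistanceMatrix,
    tolerance: float = AUDIT_TOL,
    mode: str | None = None,
    sample_size: int = 100_000,
    seed: int | None = None,
) -> MetricAuditReport:
    """Check the triangle inequality d(i,k) <= d(i,j) + d(j,k) on a matrix.

    ``mode`` is ``"exhaustive"`` (all ordered triples with j as the middle
    point) or ``"sampled"`` (``sample_size`` random triples, seeded).  When
    unset, exhaustive is chosen for matrices up to 200 items.

    Violating triples are deduplicated to unordered {i, j, k}, keeping the
    arrangement with maximal slack.
    """
    d.validate()
    n = d.n
    if mode is None:
        mode = "exhaustive" if n <= EXHAUSTIVE_LIMIT else "sampled"
    if mode not in ("exhaustive", "sampled"):
        raise ValidationError(f"unknown audit mode {mode!r}")

    M = d.values
    best: dict[frozenset, tuple[str, str, str, float]] = {}
    max_slack = -np.inf
    triples_checked = 0

    if mode == "exhaustive":
        for j in range(n):
            # slack[i, k] = d(i, k) - d(i, j) - d(j, k) for middle point j
            slack = M - M[:, j][:, None] - M[j, :][None, :]
            idx = np.arange(n)
            slack[idx, idx] = -np.inf
            slack[j, :] = -np.inf
            slack[:, j] = -np.inf
            triples_checked += (n - 1) * (n - 2)
            max_slack = max(max_slack, float(slack.max(initial=-np.inf)))
            for i, k in zip(*np.nonzero(slack > tolerance)):
                key = frozenset((i, j, k))
                cand = (d.items[i], d.items[j], d.items[k], float(slack[i, k]))
                if key not in best or cand[3] > best[key][3]:
                    best[key] = cand
    else:
        if sample_size <= 0:
            raise ValidationError("sample_size must be positive in sampled mode")
        rng = np.random.default_rng(seed)
        for _ in range(sample_size):
            i, j, k = rng.choice(n, size=3, replace=False)
            triples_checked += 1
            slack = float(M[i, k] - M[i, j] - M[j, k])
            max_slack = max(max_slack, slack)
            if slack > tolerance:
                key = frozenset((int(i), int(j), int(k)))
                cand = (d.items[i], d.items[j], d.items[k], slack)
                if key not in best or cand[3] > best[key][3]:
                    best[key] = cand

    violations = sorted(best.values(), key=lambda t: -t[3])
    if triples_checked == 0:
        max_slack = 0.0
    return MetricAuditReport(
        triples_checked=triples_checked,
        violations=violations,
        max_slack=float(max_slack),
        mode=mode,
        tolerance=tolerance,
        seed=seed if mode == "sampled" else None,
        distance_kind=d.distance_kind,
        alpha=d.alpha,
    )
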
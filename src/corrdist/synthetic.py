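"""Synthetic expression matrices with planted correlation structure.

Each planted cluster is an *archetype* profile (standard-normal draws,
scaled to unit norm); a member item is ``s * a * archetype + noise`` with a
strictly positive gain ``a``, a sign ``s`` flipped to -1 with probability
``flip_prob``, and i.i.d. Gaussian noise.  Because Pearson correlation is
invariant under positive scaling, a noiseless member is perfectly
correlated (rho = +1 or -1) with its archetype, so absolute-correlation
distances (d_a, d_r) put it at distance 0 while the signed d_o pushes a
flipped member to distance 1.  Ground truth assigns members to their
archetype regardless of sign -- exactly the "negative correlation is as
meaningful as positive" premise the distance family is designed for.

This emulates co-expression structure only: there is no count noise,
dropout, library-size variation, or temporal autocorrelation, so passing
tests demonstrate correctness of the distance/clustering machinery, not
performance on real sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import Partition
from .errors import ValidationError

__all__ = ["PlantedDesign", "generate", "generate_random_triples"]


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of a planted-cluster expression matrix.

    noise_sd is the standard deviation of additive Gaussian noise per
    entry, on the scale of a unit-norm archetype spread over n_dims
    dimensions (entries of order 1/sqrt(n_dims)); scale_range is the
    interval of strictly positive per-item gains.
    """

    n_items: int = 60
    n_dims: int = 20
    k: int = 3
    noise_sd: float = 0.0
    flip_prob: float = 0.0
    scale_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.k < 1 or self.k > self.n_items:
            raise ValidationError("need 1 <= k <= n_items")
        if self.n_dims < 3:
            raise ValidationError("need n_dims >= 3")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValidationError("flip_prob must be in [0, 1]")
        if self.noise_sd < 0.0:
            raise ValidationError("noise_sd must be nonnegative")
        lo, hi = self.scale_range
        if not 0.0 < lo <= hi:
            raise ValidationError("scale_range must be a positive interval")


def _draw_archetype(rng: np.random.Generator, n_dims: int) -> np.ndarray:
    # degenerate (constant or zero) draws have measure zero but are retried
    for _ in range(100):
        a = rng.standard_normal(n_dims)
        if np.ptp(a) > 0 and np.linalg.norm(a) > 0:
            return a / np.linalg.norm(a)
    raise ValidationError("could not draw a nondegenerate archetype")


def generate(design: PlantedDesign):
    """Generate (expression matrix, ground-truth partition, flip flags).

    Items are dealt to the k archetypes round-robin, so every planted
    cluster is nonempty and sizes differ by at most one.  Fully
    reproducible from ``design.seed``.

    Returns
    -------
    matrix : pandas.DataFrame
        n_items x n_dims, rows ``item_0 .. item_{n-1}``.
    truth : Partition
        item -> planted cluster, ignoring sign flips.
    flips : dict[str, bool]
        item -> whether its sign was flipped.
    """
    rng = np.random.default_rng(design.seed)
    archetypes = np.stack([_draw_archetype(rng, design.n_dims) for _ in range(design.k)])
    items = [f"item_{i}" for i in range(design.n_items)]
    membership = np.arange(design.n_items) % design.k
    gains = rng.uniform(*design.scale_range, size=design.n_items)
    flips = rng.random(design.n_items) < design.flip_prob
    signs = np.where(flips, -1.0, 1.0)
    noise = rng.normal(0.0, design.noise_sd, size=(design.n_items, design.n_dims))
    values = signs[:, None] * gains[:, None] * archetypes[membership] + noise
    matrix = pd.DataFrame(values, index=items, columns=[f"dim_{j}" for j in range(design.n_dims)])
    truth = Partition.from_labels(items, membership)
    return matrix, truth, dict(zip(items, map(bool, flips)))


def generate_random_triples(n_triples: int, n_dims: int, seed: int = 0):
    """i.i.d. standard-normal profile triples, fuel for metric fuzz tests."""
    if n_dims < 3:
        raise ValidationError("need n_dims >= 3")
    rng = np.random.default_rng(seed)
    triples = []
    for _ in range(n_triples):
        t = rng.standard_normal((3, n_dims))
        while any(np.ptp(row) == 0 for row in t):  # measure-zero guard
            t = rng.standard_normal((3, n_dims))
        triples.append(t)
    return triples
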
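"""Bootstrap stability of correlation-distance clusterings.

The pipeline resamples the items of an expression matrix with replacement
(at the original size n), re-clusters each resample, and summarizes how
well the original clustering survives:

* **Class dissolution.**  For each original class and each bootstrap, the
  best Jaccard similarity J between the class (restricted to the items that
  were actually resampled) and any bootstrap class is recorded.  The class
  *dissolves* in a bootstrap when J < 0.5 (strict); it counts as dissolved
  in the experiment when this happens in more than 40 of 100 bootstraps
  (strict).  Fewer dissolved classes means a more stable clustering.

* **Sample-pair consistency (upsilon).**  For every item pair, count n1 =
  bootstraps where both were sampled, n2 = of those, times they landed in
  the same class, n3 = times in different classes.  Pairs with n2 > n3 are
  oriented "together", otherwise "apart".  upsilon is the product of the
  median n2/n1 over together-pairs and the median n3/n1 over apart-pairs
  (nonzero ratios only); it is 1 for a perfectly reproducible clustering.

Two distance kinds are compared by running the whole pipeline for each
over the *same* resamples, recording a win whenever one upsilon exceeds the
other, and testing the paired upsilon lists with a Wilcoxon signed-rank
test.  Everything is a pure function of (data, recipe, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clustering import Partition, cut, hierarchical, pam
from .correlations import CorrelationKind
from .distances import DistanceKind, distance_matrix
from .errors import CorrdistError, ValidationError
from .evaluation import PairedSummary, paired_differences

__all__ = [
    "ClusteringRecipe",
    "BootstrapConfig",
    "BootstrapReplicate",
    "DissolutionResult",
    "PairConsistencyResult",
    "DistanceComparison",
    "jaccard",
    "cluster_matrix",
    "bootstrap_run",
    "dissolution",
    "pair_consistency",
    "compare_distances",
]


@dataclass(frozen=True)
class ClusteringRecipe:
    """Everything needed to turn an expression matrix into a partition."""

    method: str = "pam"  # "pam" or "hierarchical"
    correlation_kind: CorrelationKind = CorrelationKind.PEARSON
    distance_kind: DistanceKind = DistanceKind.D_R
    k: int = 3
    linkage: str = "average"
    alpha: float | None = None

    def __post_init__(self):
        if self.method not in ("pam", "hierarchical"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.k < 1:
            raise ValidationError("k must be >= 1")


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap experiment parameters.

    Defaults follow the standard protocol: 100 bootstraps per experiment,
    20 independent iterations, dissolution thresholds J < 0.5 and
    count > 40 (both strict).
    """

    n_bootstraps: int = 100
    n_iterations: int = 20
    dissolve_jaccard: float = 0.5
    dissolve_count: int = 40
    seed: int = 0
    restrict_to_sampled: bool = True

    def __post_init__(self):
        if self.n_bootstraps < 1 or self.n_iterations < 1:
            raise ValidationError("n_bootstraps and n_iterations must be >= 1")
        if not 0.0 < self.dissolve_jaccard < 1.0:
            raise ValidationError("dissolve_jaccard must be in (0, 1)")
        if not 0 < self.dissolve_count <= self.n_bootstraps:
            raise ValidationError("dissolve_count must be in (0, n_bootstraps]")


def jaccard(a, b) -> float:
    """|a & b| / |a | b| on sets; 0 against an empty b, error on empty a."""
    a, b = set(a), set(b)
    if not a:
        raise ValidationError("first set must be nonempty")
    if not b:
        return 0.0
    return len(a & b) / len(a | b)


def cluster_matrix(matrix: pd.DataFrame, recipe: ClusteringRecipe) -> Partition:
    """Run a recipe end to end: distance matrix, then PAM or a dendrogram cut."""
    d = distance_matrix(
        matrix, ckind=recipe.correlation_kind, dkind=recipe.distance_kind,
        alpha=recipe.alpha,
    )
    if recipe.method == "pam":
        return pam(d, recipe.k).partition
    return cut(hierarchical(d, linkage=recipe.linkage), recipe.k)


@dataclass
class BootstrapReplicate:
    """One resample and its clustering, mapped back to original item ids.

    Duplicated draws are retained as distinct rows while clustering; for
    scoring, ``classes`` collapses each bootstrap class to the *set* of
    original ids of its members, and ``first_copy_label`` assigns each
    sampled original item the cluster of its first-drawn copy (a
    deterministic rule for pair counting when copies disagree).
    """

    indices: np.ndarray  # resampled row positions, length n
    sampled_items: set[str]
    classes: dict[int, set[str]]
    first_copy_label: dict[str, int]


def bootstrap_run(
    matrix: pd.DataFrame,
    recipe: ClusteringRecipe,
    cfg: BootstrapConfig,
    seed: int | None = None,
) -> list[BootstrapReplicate]:
    """Resample n items with replacement and re-cluster, cfg.n_bootstraps times.

    A resample on which the recipe fails (for example a degenerate profile
    after duplication) is redrawn, up to 10 times, before giving up.
    Reproducible from the seed (``cfg.seed`` unless overridden).
    """
    n = matrix.shape[0]
    if recipe.k > n:
        raise ValidationError(f"k={recipe.k} exceeds n={n}")
    items = [str(i) for i in matrix.index]
    values = matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    out: list[BootstrapReplicate] = []
    for _ in range(cfg.n_bootstraps):
        last_err: Exception | None = None
        for _attempt in range(10):
            idx = rng.integers(0, n, size=n)
            resampled = pd.DataFrame(
                values[idx],
                index=[f"{items[i]}::copy{t}" for t, i in enumerate(idx)],
                columns=matrix.columns,
            )
            try:
                part = cluster_matrix(resampled, recipe)
            except CorrdistError as e:
                last_err = e
                continue
            labels = part.labels_for(resampled.index)
            classes: dict[int, set[str]] = {}
            first_copy: dict[str, int] = {}
            for t, i in enumerate(idx):
                classes.setdefault(int(labels[t]), set()).add(items[i])
                first_copy.setdefault(items[i], int(labels[t]))
            out.append(
                BootstrapReplicate(
                    indices=idx,
                    sampled_items={items[i] for i in idx},
                    classes=classes,
                    first_copy_label=first_copy,
                )
            )
            break
        else:
            raise CorrdistError(
                f"recipe failed on 10 consecutive resamples: {last_err}"
            )
    return out


@dataclass
class DissolutionResult:
    """Per-class dissolution counts over a bootstrap experiment."""

    per_class: dict[int, dict]
    n_dissolved: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": c, **stats} for c, stats in sorted(self.per_class.items())
        ]
        return pd.DataFrame(rows)


def dissolution(
    p_o: Partition, runs: list[BootstrapReplicate], cfg: BootstrapConfig
) -> DissolutionResult:
    """Count, per original class, the bootstraps in which it dissolved.

    For bootstrap i and original class c, J_i(c) is the maximum Jaccard
    similarity between c and any bootstrap class; c dissolves in i when
    J_i(c) < cfg.dissolve_jaccard.  A bootstrap in which no member of c was
    sampled is skipped for c (and recorded).  The class is dissolved
    overall when its dissolve count strictly exceeds cfg.dissolve_count.
    """
    if not runs:
        raise ValidationError("no bootstrap runs")
    per_class: dict[int, dict] = {}
    for label, members in p_o.classes().items():
        count = skipped = 0
        for rep in runs:
            ref = members & rep.sampled_items if cfg.restrict_to_sampled else members
            if not ref:
                skipped += 1
                continue
            j_best = max(jaccard(ref, c) for c in rep.classes.values())
            if j_best < cfg.dissolve_jaccard:
                count += 1
        per_class[label] = {
            "dissolve_count": count,
            "skipped": skipped,
            "dissolved": count > cfg.dissolve_count,
        }
    return DissolutionResult(
        per_class=per_class,
        n_dissolved=sum(1 for s in per_class.values() if s["dissolved"]),
    )


@dataclass
class PairConsistencyResult:
    """Per-pair co-clustering counts and the upsilon summary."""

    per_pair: pd.DataFrame = field(repr=False)  # item_a, item_b, n1, n2, n3, orientation
    m_together: float
    m_not_together: float
    upsilon: float


def pair_consistency(
    p_o: Partition, runs: list[BootstrapReplicate]
) -> PairConsistencyResult:
    """upsilon = median(n2/n1 | together-pairs) * median(n3/n1 | apart-pairs).

    Pair membership in a bootstrap uses the first-drawn copy of each item.
    Pairs never co-sampled (n1 = 0) are excluded; medians run over nonzero
    ratios only.  Raises when either orientation has no pairs, in which
    case upsilon is undefined.
    """
    if not runs:
        raise ValidationError("no bootstrap runs")
    items = sorted(p_o.assignment)
    pos = {it: i for i, it in enumerate(items)}
    n = len(items)
    n1 = np.zeros((n, n), dtype=int)
    n2 = np.zeros((n, n), dtype=int)
    for rep in runs:
        labels = np.full(n, -1, dtype=int)
        for it, lab in rep.first_copy_label.items():
            labels[pos[it]] = lab
        sampled = labels >= 0
        co = sampled[:, None] & sampled[None, :]
        same = co & (labels[:, None] == labels[None, :])
        n1 += co
        n2 += same
    iu = np.triu_indices(n, k=1)
    n1u, n2u = n1[iu], n2[iu]
    n3u = n1u - n2u
    keep = n1u > 0
    rows = pd.DataFrame(
        {
            "item_a": np.array(items)[iu[0]][keep],
            "item_b": np.array(items)[iu[1]][keep],
            "n1": n1u[keep],
            "n2": n2u[keep],
            "n3": n3u[keep],
        }
    )
    rows["orientation"] = np.where(rows["n2"] > rows["n3"], "together", "apart")
    tog = rows.loc[rows["orientation"] == "together"]
    apart = rows.loc[rows["orientation"] == "apart"]
    tog_ratios = (tog["n2"] / tog["n1"]).to_numpy()
    apart_ratios = (apart["n3"] / apart["n1"]).to_numpy()
    tog_ratios = tog_ratios[tog_ratios > 0]
    apart_ratios = apart_ratios[apart_ratios > 0]
    if tog_ratios.size == 0 or apart_ratios.size == 0:
        raise CorrdistError("upsilon undefined: an orientation has no pairs")
    m_t = float(np.median(tog_ratios))
    m_nt = float(np.median(apart_ratios))
    return PairConsistencyResult(
        per_pair=rows, m_together=m_t, m_not_together=m_nt, upsilon=m_t * m_nt
    )


@dataclass
class DistanceComparison:
    """Iteration-by-iteration comparison of two distance kinds."""

    upsilon_a: list[float]
    upsilon_b: list[float]
    dissolved_a: list[int]
    dissolved_b: list[int]
    n_win_a: int
    n_win_b: int
    n_tie: int
    upsilon_test: PairedSummary
    iteration_seeds: list[int]

    def to_dict(self) -> dict:
        return {
            "upsilon_a": self.upsilon_a,
            "upsilon_b": self.upsilon_b,
            "dissolved_a": self.dissolved_a,
            "dissolved_b": self.dissolved_b,
            "n_win_a": self.n_win_a,
            "n_win_b": self.n_win_b,
            "n_tie": self.n_tie,
            "upsilon_p_value": self.upsilon_test.p_value,
            "iteration_seeds": self.iteration_seeds,
        }


def iteration_seeds(seed: int, n_iterations: int) -> list[int]:
    """Independent, reproducible child seeds (below 2**31) for each iteration."""
    state = np.random.SeedSequence(seed).generate_state(n_iterations, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def compare_distances(
    matrix: pd.DataFrame,
    recipe_a: ClusteringRecipe,
    recipe_b: ClusteringRecipe,
    cfg: BootstrapConfig,
) -> DistanceComparison:
    """Run the full stability pipeline for two distance kinds and compare.

    The recipes must differ only in distance kind (and alpha).  Each of
    cfg.n_iterations iterations draws its own resamples; both recipes see
    the *same* resamples within an iteration, so the per-iteration upsilon
    values are paired.  A win for a recipe is an iteration where its
    upsilon is strictly larger.
    """
    if replace(recipe_a, distance_kind=recipe_b.distance_kind, alpha=recipe_b.alpha) != recipe_b:
        raise ValidationError("recipes must differ only in distance kind")
    p_a = cluster_matrix(matrix, recipe_a)
    p_b = cluster_matrix(matrix, recipe_b)
    seeds = iteration_seeds(cfg.seed, cfg.n_iterations)
    ups_a, ups_b, dis_a, dis_b = [], [], [], []
    for s in seeds:
        runs_a = bootstrap_run(matrix, recipe_a, cfg, seed=s)
        runs_b = bootstrap_run(matrix, recipe_b, cfg, seed=s)
        ups_a.append(pair_consistency(p_a, runs_a).upsilon)
        ups_b.append(pair_consistency(p_b, runs_b).upsilon)
        dis_a.append(dissolution(p_a, runs_a, cfg).n_dissolved)
        dis_b.append(dissolution(p_b, runs_b, cfg).n_dissolved)
    wins_a = sum(1 for a, b in zip(ups_a, ups_b) if a > b)
    wins_b = sum(1 for a, b in zip(ups_a, ups_b) if b > a)
    return DistanceComparison(
        upsilon_a=ups_a,
        upsilon_b=ups_b,
        dissolved_a=dis_a,
        dissolved_b=dis_b,
        n_win_a=wins_a,
        n_win_b=wins_b,
        n_tie=cfg.n_iterations - wins_a - wins_b,
        upsilon_test=paired_differences(ups_a, ups_b),
        iteration_seeds=seeds,
    )
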
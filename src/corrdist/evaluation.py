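"""Scoring partitions and comparing enrichment results.

* :func:`adjusted_rand_index` -- chance-corrected agreement between two
  partitions of the same items (1 = identical up to relabeling, 0 =
  expectation under the permutation model).
* :func:`compare_pvalue_lists` -- given two term -> p-value tables (for
  instance GO enrichment results from two clusterings of the same genes),
  counts on the shared terms how often each side has the strictly smaller
  p-value and reports ``log(#(r1 < r2) / #(r2 < r1))``.  Positive means the
  first list wins; swapping the arguments flips only the sign.
* :func:`paired_differences` -- per-pair win/loss/tie counts plus a
  Wilcoxon signed-rank test, for comparing two matched score lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import wilcoxon
from sklearn.metrics import adjusted_rand_score

from .clustering import Partition
from .errors import ValidationError

__all__ = [
    "PValueList",
    "ComparisonResult",
    "PairedSummary",
    "adjusted_rand_index",
    "compare_pvalue_lists",
    "paired_differences",
]


def adjusted_rand_index(p1: Partition, p2: Partition) -> float:
    """ARI between two partitions of the same item set."""
    if set(p1.assignment) != set(p2.assignment):
        raise ValidationError("partitions cover different item sets")
    items = sorted(p1.assignment)
    return float(adjusted_rand_score(p1.labels_for(items), p2.labels_for(items)))


@dataclass(frozen=True)
class PValueList:
    """A term -> p-value table, p in (0, 1]."""

    entries: dict

    def __post_init__(self):
        entries = {str(t): float(p) for t, p in dict(self.entries).items()}
        for term, p in entries.items():
            if not 0.0 < p <= 1.0:
                raise ValidationError(f"p-value for {term!r} must be in (0, 1], got {p}")
        object.__setattr__(self, "entries", entries)

    def significant(self, alpha: float = 0.05) -> "PValueList":
        return PValueList({t: p for t, p in self.entries.items() if p < alpha})

    @classmethod
    def read(cls, path) -> "PValueList":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))))

    def write(self, path):
        pd.DataFrame(
            {"term": list(self.entries), "p": list(self.entries.values())}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ComparisonResult:
    """Counts and log-ratio statistic of a paired p-value comparison."""

    n_first_smaller: int
    n_second_smaller: int
    n_ties: int
    n_shared: int
    n_only_first: int
    n_only_second: int
    statistic: float  # natural log of the count ratio; +/-inf if one count is 0


def compare_pvalue_lists(r1: PValueList, r2: PValueList) -> ComparisonResult:
    """Log-ratio comparison of two term -> p-value lists on their shared terms.

    Counts, over terms present in both lists, how often r1's p-value is
    strictly smaller than r2's and vice versa (equal p-values count for
    neither side), then returns ``ln(#(r1 < r2) / #(r2 < r1))``.  If exactly
    one count is zero the statistic is signed infinity; if both are zero no
    direction exists and an error is raised.
    """
    shared = sorted(set(r1.entries) & set(r2.entries))
    if not shared:
        raise ValidationError("no shared terms between the two lists")
    n1 = sum(1 for t in shared if r1.entries[t] < r2.entries[t])
    n2 = sum(1 for t in shared if r2.entries[t] < r1.entries[t])
    ties = len(shared) - n1 - n2
    if n1 == 0 and n2 == 0:
        raise ValidationError("all shared terms tie; comparison undefined")
    if n2 == 0:
        stat = math.inf
    elif n1 == 0:
        stat = -math.inf
    else:
        stat = math.log(n1 / n2)
    return ComparisonResult(
        n_first_smaller=n1,
        n_second_smaller=n2,
        n_ties=ties,
        n_shared=len(shared),
        n_only_first=len(set(r1.entries) - set(r2.entries)),
        n_only_second=len(set(r2.entries) - set(r1.entries)),
        statistic=stat,
    )


@dataclass(frozen=True)
class PairedSummary:
    """Win/loss/tie counts for matched score lists, with a signed-rank test."""

    n_win_a: int
    n_win_b: int
    n_tie: int
    p_value: float | None  # None when every pair ties (test undefined)


def paired_differences(scores_a, scores_b) -> PairedSummary:
    """Signs of a - b plus a Wilcoxon signed-rank test on the nonzero differences."""
    a, b = list(map(float, scores_a)), list(map(float, scores_b))
    if len(a) != len(b):
        raise ValidationError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValidationError("empty score lists")
    diffs = [x - y for x, y in zip(a, b)]
    n_win_a = sum(1 for d in diffs if d > 0)
    n_win_b = sum(1 for d in diffs if d < 0)
    n_tie = len(diffs) - n_win_a - n_win_b
    nonzero = [d for d in diffs if d != 0]
    p_value = float(wilcoxon(nonzero).pvalue) if nonzero else None
    return PairedSummary(n_win_a=n_win_a, n_win_b=n_win_b, n_tie=n_tie, p_value=p_value)
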
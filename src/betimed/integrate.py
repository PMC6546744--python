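"""Three-way evidence integration and gene-set overlap statistics.

A *mediator* gene is one that is (i) transcriptionally suppressed by drug,
(ii) essential in the knockout screen, and (iii) sufficient to rescue the
drug effect when overexpressed.  This module intersects the three evidence
layers over a declared gene universe and quantifies pairwise overlaps with a
one-sided Fisher exact (hypergeometric tail) test or a Pearson chi-square
test on the 2x2 membership table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OverlapResult",
    "MediatorSet",
    "classify_genes",
    "overlap_fisher",
    "overlap_chisq",
]


@dataclass
class OverlapResult:
    universe: int
    n_a: int
    n_b: int
    overlap: int
    expected: float
    statistic: float
    p_value: float
    method: str


@dataclass
class MediatorSet:
    mediators: set[str]
    suppressed_and_essential: set[str]
    suppressed_and_rescue: set[str]
    essential_and_rescue: set[str]
    universe_size: int


def _check_counts(n_a: int, n_b: int, k: int, n: int) -> None:
    if not (0 <= k <= min(n_a, n_b)):
        raise ValueError(f"overlap {k} exceeds min set size {min(n_a, n_b)}")
    if n_a > n or n_b > n:
        raise ValueError("set size exceeds universe")
    if min(n_a, n_b, n) < 0:
        raise ValueError("negative counts")


def overlap_fisher(n_a: int, n_b: int, k: int, universe: int) -> OverlapResult:
    """One-sided (enrichment) Fisher exact p: hypergeometric P(X >= k)."""
    _check_counts(n_a, n_b, k, universe)
    p = float(stats.hypergeom.sf(k - 1, universe, n_a, n_b))
    expected = n_a * n_b / universe
    return OverlapResult(universe, n_a, n_b, k, expected, float(k - expected), min(p, 1.0), "fisher")


def overlap_chisq(n_a: int, n_b: int, k: int, universe: int) -> OverlapResult:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 membership table."""
    _check_counts(n_a, n_b, k, universe)
    table = np.array(
        [
            [k, n_a - k],
            [n_b - k, universe - n_a - n_b + k],
        ]
    )
    if np.any(table < 0):
        raise ValueError("inconsistent counts: negative 2x2 cell")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected < 1):
        raise ValueError("expected cell count < 1; use overlap_fisher instead")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return OverlapResult(
        universe, n_a, n_b, k, float(expected[0, 0]), float(chi2), float(p), "chisq"
    )


def classify_genes(
    suppressed: set[str],
    essential: set[str],
    rescue: set[str],
    universe: set[str],
    q_only_rescue: set[str] | None = None,
) -> tuple[pd.DataFrame, MediatorSet]:
    """Per-gene evidence triple over ``universe`` plus the triple intersection.

    ``q_only_rescue`` genes passed the rescue q threshold but not the LFC
    threshold; they are reported as a separate flag, never as mediators.
    """
    q_only_rescue = q_only_rescue or set()
    for name, s in (
        ("suppressed", suppressed),
        ("essential", essential),
        ("rescue", rescue),
        ("q_only_rescue", q_only_rescue),
    ):
        outside = s - universe
        if outside:
            raise ValueError(
                f"{name} gene(s) outside universe: {sorted(outside)[:5]}"
            )
    genes = sorted(universe)
    evidence = pd.DataFrame(
        {
            "gene": genes,
            "suppressed": [g in suppressed for g in genes],
            "essential": [g in essential for g in genes],
            "rescue": [g in rescue for g in genes],
            "q_only_rescue": [g in q_only_rescue for g in genes],
        }
    ).set_index("gene", drop=False)
    evidence.index.name = None
    mediators = suppressed & essential & rescue
    med = MediatorSet(
        mediators=mediators,
        suppressed_and_essential=suppressed & essential,
        suppressed_and_rescue=suppressed & rescue,
        essential_and_rescue=essential & rescue,
        universe_size=len(universe),
    )
    return evidence, med
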
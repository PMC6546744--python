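"""Comparative marker selection: SNR statistic, permutation p-values, FDR calls.

The differential-expression layer scores each feature (gene, or chromatin
mark) with a signal-to-noise ratio between two sample groups,

    SNR = (mu_A - mu_B) / (sigma'_A + sigma'_B),

where each group's sample standard deviation is floored at a fraction of the
group-mean magnitude (variance stabilization for low-variance features).
Significance comes from a label-permutation null: all distinct group
labelings are enumerated exactly when there are few enough, otherwise a
seeded random sample of labelings is drawn.  Expression mode applies
Benjamini-Hochberg q-values with a p < 0.05 and q < 0.1 call; chromatin mode
uses Bonferroni-adjusted values with a 0.1 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MarkerConfig",
    "snr_statistic",
    "permutation_pvalues",
    "call_markers",
    "run_marker_selection",
]


@dataclass
class MarkerConfig:
    n_permutations: int = 1000
    seed: int = 0
    sigma_floor_fraction: float = 0.2
    p_threshold: float = 0.05
    q_threshold: float = 0.1
    correction: str = "BH"          # "BH" (expression) or "Bonferroni" (chromatin)
    bonferroni_q: float = 0.1
    exact_limit: int = 10_000       # enumerate all labelings when their count <= this

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        for name in ("p_threshold", "q_threshold", "bonferroni_q"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.correction not in {"BH", "Bonferroni"}:
            raise ValueError("correction must be 'BH' or 'Bonferroni'")


def _floored_sd(values: np.ndarray, floor_fraction: float, axis=-1) -> np.ndarray:
    sd = values.std(axis=axis, ddof=1)
    mu = values.mean(axis=axis)
    return np.maximum.reduce([sd, floor_fraction * np.abs(mu), np.full_like(sd, 1e-8)])


def snr_statistic(
    group_a: np.ndarray, group_b: np.ndarray, sigma_floor_fraction: float = 0.2
) -> float | np.ndarray:
    """Signal-to-noise ratio; accepts 1-D vectors or feature x sample matrices."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[-1] < 2 or b.shape[-1] < 2:
        raise ValueError("each group needs >= 2 samples")
    num = a.mean(axis=-1) - b.mean(axis=-1)
    den = _floored_sd(a, sigma_floor_fraction) + _floored_sd(b, sigma_floor_fraction)
    out = num / den
    return float(out) if out.ndim == 0 else out


def _labelings(n: int, n_a: int, cfg: MarkerConfig, rng: np.random.Generator):
    """Yield (indices_of_group_A, exact_flag)."""
    from math import comb

    total = comb(n, n_a)
    if total <= cfg.exact_limit:
        return [np.asarray(c) for c in combinations(range(n), n_a)], True
    draws = [np.sort(rng.choice(n, size=n_a, replace=False)) for _ in range(cfg.n_permutations)]
    return draws, False


def permutation_pvalues(
    matrix: pd.DataFrame | np.ndarray,
    labels: np.ndarray | list,
    config: MarkerConfig | None = None,
) -> tuple[pd.Series | np.ndarray, np.ndarray]:
    """Two-sided permutation p per feature for the SNR statistic.

    ``labels`` is a boolean/0-1 vector over samples (True = group A).  Exact
    mode: p = (#labelings with |SNR| >= observed) / (#labelings) — the
    observed labeling is one of them, so p >= 1/#labelings.  Sampled mode adds
    the +1 smoothing: p = (1 + #exceedances) / (1 + n_permutations).

    Returns (p, observed_snr).
    """
    cfg = config or MarkerConfig()
    values = matrix.to_numpy(float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    lab = np.asarray(labels).astype(bool)
    if lab.size != values.shape[1]:
        raise ValueError("label vector length must match number of samples")
    n_a = int(lab.sum())
    if n_a == 0 or n_a == lab.size:
        raise ValueError("both groups must be non-empty")
    idx_a = np.flatnonzero(lab)
    observed = snr_statistic(values[:, idx_a], values[:, ~lab], cfg.sigma_floor_fraction)
    obs_abs = np.abs(observed)

    rng = np.random.default_rng(cfg.seed)
    perms, exact = _labelings(lab.size, n_a, cfg, rng)
    all_idx = np.arange(lab.size)
    exceed = np.zeros(values.shape[0], dtype=np.int64)
    for a_idx in perms:
        mask = np.zeros(lab.size, dtype=bool)
        mask[a_idx] = True
        snr = snr_statistic(
            values[:, mask], values[:, all_idx[~mask]], cfg.sigma_floor_fraction
        )
        exceed += np.abs(snr) >= obs_abs - 1e-12
    if exact:
        p = exceed / len(perms)
    else:
        p = (1 + exceed) / (1 + len(perms))
    if isinstance(matrix, pd.DataFrame):
        return pd.Series(p, index=matrix.index), observed
    return p, observed


def call_markers(
    p_values: pd.Series,
    snr: pd.Series,
    config: MarkerConfig | None = None,
) -> pd.DataFrame:
    """Adjust p-values and flag significant features with their direction.

    Direction "down" means group B (e.g. drug) mean below group A with the
    convention SNR = mu_A - mu_B... here SNR > 0 means group A higher; callers
    pass (vehicle, drug) ordering so SNR > 0 marks drug-suppressed features.
    """
    cfg = config or MarkerConfig()
    p = p_values.astype(float)
    if cfg.correction == "BH":
        adj = pd.Series(multipletests(p.to_numpy(), method="fdr_bh")[1], index=p.index)
        significant = (p < cfg.p_threshold) & (adj < cfg.q_threshold)
    else:
        adj = pd.Series(np.minimum(p.to_numpy() * len(p), 1.0), index=p.index)
        significant = adj < cfg.bonferroni_q
    snr = snr.reindex(p.index)
    return pd.DataFrame(
        {
            "feature": p.index,
            "snr": snr.to_numpy(),
            "p": p.to_numpy(),
            "q": adj.to_numpy(),
            "direction": np.where(snr.to_numpy() > 0, "down", "up"),
            "significant": significant.to_numpy(),
        }
    ).set_index("feature", drop=False)


def run_marker_selection(
    matrix: pd.DataFrame,
    labels,
    config: MarkerConfig | None = None,
) -> pd.DataFrame:
    """Full layer: SNR -> permutation p -> adjusted calls.

    ``labels`` marks group A (reference/vehicle) samples True; features with a
    significant positive SNR are the drug-suppressed set.
    """
    cfg = config or MarkerConfig()
    p, observed = permutation_pvalues(matrix, labels, cfg)
    stats_table = call_markers(p, pd.Series(observed, index=matrix.index), cfg)
    stats_table.index.name = None
    return stats_table


def suppressed_set(marker_stats: pd.DataFrame) -> set[str]:
    """Features significantly *down* under drug (positive SNR with vehicle first)."""
    mask = marker_stats["significant"] & (marker_stats["direction"] == "down")
    return set(marker_stats.index[mask])


def top_suppressed(marker_stats: pd.DataFrame, n: int) -> set[str]:
    """Rank-by-SNR alternative selection: the n most drug-suppressed features."""
    return set(marker_stats.sort_values("snr", ascending=False).head(n).index)
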
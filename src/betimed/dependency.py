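"""Gene dependency scoring and the two-component empirical mixture model.

A pooled CRISPR knockout screen measures, per guide, the log2 fold change
(LFC) of read abundance between a final time point and an early reference.
Guides are collapsed to a per-gene *dependency score* (median of guides; more
negative = more depleted = more essential).  The probability that a score
reflects a true dependency is obtained from a two-component mixture:

* the "dependent" component density is estimated empirically from the scores
  of *pan-essential* genes (genes in the bottom quantile of scores across
  nearly all lines of a reference panel),
* the "non-dependent" component density from genes not expressed in the line
  (knocking out an unexpressed gene should be neutral),
* the mixing weight ``pi`` is fitted by EM over all gene scores with the two
  component densities held fixed.

The raw posterior P(dependent | score) is then post-processed in this order:
hard tail clamps (score < -1.5 -> probability 1, score > 0.25 -> 0), Gaussian
smoothing of the probability-versus-score curve (sd 0.15 score units), a
re-clip to [0, 1] with the clamps re-imposed exactly, and finally a monotone
non-increasing projection so that a more negative score can never receive a
lower probability.

Genes are called essential when probability > 0.35 and an FDR-style q-value
(< 0.2) both pass; the q-value at rank i of the descending-probability
ordering is the running mean of (1 - probability) over ranks 1..i, the usual
local-FDR to tail-FDR aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gaussian_kde

from .io import CountTable

__all__ = [
    "DependencyConfig",
    "DependencyModel",
    "DependencyCall",
    "compute_guide_lfc",
    "aggregate_gene_scores",
    "derive_pan_essential",
    "fit_dependency_model",
    "dependency_probability",
    "call_essentials",
    "score_screen",
]


@dataclass
class DependencyConfig:
    clamp_low: float = -1.5
    clamp_high: float = 0.25
    smooth_sigma: float = 0.15          # sd of the smoothing kernel, score units
    prob_threshold: float = 0.35
    fdr_threshold: float = 0.2
    pan_quantile: float = 0.26
    pan_fraction: float = 0.90
    unexpressed_cutoff: float = 0.2     # log2 normalized expression below which a gene is "not expressed"
    pseudocount: float = 1.0
    min_anchor_size: int = 20
    grid_points: int = 512
    grid_pad: float = 1.0
    fixed_pi: float | None = None       # skip EM and use this mixing weight
    enforce_monotone: bool = True

    def __post_init__(self) -> None:
        if not self.clamp_low < self.clamp_high:
            raise ValueError("clamp_low must be < clamp_high")
        if self.smooth_sigma <= 0:
            raise ValueError("smooth_sigma must be > 0")
        for name in ("prob_threshold", "fdr_threshold", "pan_quantile", "pan_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


def compute_guide_lfc(
    counts: CountTable,
    final_samples: list[str],
    reference_samples: list[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-guide LFC: mean log2(RPM + pseudocount) of final minus reference samples."""
    if not final_samples or not reference_samples:
        raise ValueError("need at least one final and one reference sample")
    frame = counts.to_frame()
    for s in final_samples + reference_samples:
        if s not in frame.columns:
            raise KeyError(f"sample {s!r} not in count table")
        if frame[s].sum() == 0:
            raise ValueError(f"sample {s!r} has zero total reads")
    rpm = frame / frame.sum(axis=0) * 1e6
    log = np.log2(rpm + pseudocount)
    return log[final_samples].mean(axis=1) - log[reference_samples].mean(axis=1)


def aggregate_gene_scores(
    guide_lfc: pd.Series,
    guide_map: dict[str, tuple[str, bool]],
    method: str = "median",
) -> pd.Series:
    """Collapse guide LFCs to gene scores; non-targeting guides are excluded.

    ``guide_map`` maps guide id -> (gene, is_control).  Every guide in the LFC
    table must be mapped and every gene must retain >= 1 guide.
    """
    unmapped = [g for g in guide_lfc.index if g not in guide_map]
    if unmapped:
        raise KeyError(f"{len(unmapped)} guides missing from guide map, e.g. {unmapped[0]!r}")
    genes: dict[str, list[float]] = {}
    for guide, lfc in guide_lfc.items():
        gene, is_control = guide_map[guide]
        if is_control:
            continue
        genes.setdefault(gene, []).append(lfc)
    if not genes:
        raise ValueError("no gene-targeting guides present")
    agg = np.median if method == "median" else np.mean
    return pd.Series({g: float(agg(v)) for g, v in sorted(genes.items())}, name="score")


def derive_pan_essential(
    scores: pd.DataFrame,
    pan_quantile: float = 0.26,
    pan_fraction: float = 0.90,
) -> set[str]:
    """Genes in the bottom ``pan_quantile`` of each line's scores in >= ``pan_fraction`` of lines.

    ``scores`` is a gene x cell-line frame.  With fewer than 2 lines the
    quantile membership rule is meaningless; callers must then provide an
    explicit pan-essential list instead.
    """
    if scores.shape[1] < 2:
        raise ValueError(
            "pan-essential derivation needs >= 2 cell lines; "
            "supply an explicit pan-essential gene list instead"
        )
    cutoffs = scores.quantile(pan_quantile, axis=0)
    in_bottom = scores.le(cutoffs, axis=1)
    frac = in_bottom.mean(axis=1)
    return set(frac.index[frac >= pan_fraction])


@dataclass
class DependencyModel:
    """Fitted mixture model: shared grid, component densities, pi, smoothed curve."""

    grid: np.ndarray
    f_dep: np.ndarray
    f_non: np.ndarray
    pi: float
    prob_curve: np.ndarray
    config: DependencyConfig = field(default_factory=DependencyConfig)

    def __post_init__(self) -> None:
        dx = float(self.grid[1] - self.grid[0])
        for name, dens in (("f_dep", self.f_dep), ("f_non", self.f_non)):
            mass = float(np.sum(dens) * dx)
            if abs(mass - 1.0) > 1e-3:
                raise ValueError(f"{name} integrates to {mass}, expected 1")
        if np.any(self.prob_curve < 0) or np.any(self.prob_curve > 1):
            raise ValueError("probability curve escapes [0, 1]")


def _kde_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    # Silverman bandwidth; density renormalized on the (finite) grid so both
    # components integrate to one over the same support.
    kde = gaussian_kde(values, bw_method="silverman")
    dens = kde(grid)
    dx = grid[1] - grid[0]
    return dens / (dens.sum() * dx)


def _em_mixing_weight(
    scores: np.ndarray, f_dep_at: np.ndarray, f_non_at: np.ndarray,
    tol: float = 1e-8, max_iter: int = 500,
) -> float:
    """EM for pi with both component densities fixed (closed-form E/M steps)."""
    eps = 1e-300
    pi = 0.5
    for _ in range(max_iter):
        num = pi * f_dep_at
        post = num / np.maximum(num + (1.0 - pi) * f_non_at, eps)
        new_pi = float(np.mean(post))
        if abs(new_pi - pi) < tol:
            pi = new_pi
            break
        pi = new_pi
    return float(np.clip(pi, 1e-6, 1 - 1e-6))


def fit_dependency_model(
    line_scores: pd.Series,
    pan_essential: set[str],
    unexpressed: set[str],
    config: DependencyConfig | None = None,
) -> DependencyModel:
    """Fit the two-component empirical mixture for one cell line.

    ``pan_essential`` anchors the dependent component, ``unexpressed`` the
    non-dependent component; both must have >= ``config.min_anchor_size``
    members with scores in this line.
    """
    cfg = config or DependencyConfig()
    scores = line_scores.dropna()
    dep_scores = scores.loc[scores.index.intersection(list(pan_essential))].to_numpy(float)
    non_scores = scores.loc[scores.index.intersection(list(unexpressed))].to_numpy(float)
    for name, anchor in (("pan-essential", dep_scores), ("unexpressed", non_scores)):
        if anchor.size < cfg.min_anchor_size:
            raise ValueError(
                f"{name} anchor set has only {anchor.size} scored genes "
                f"(need >= {cfg.min_anchor_size}); supply explicit component densities "
                "or a larger anchor list"
            )
    lo = float(scores.min()) - cfg.grid_pad
    hi = float(scores.max()) + cfg.grid_pad
    # the clamp boundaries must lie inside the grid so the clamps are representable
    lo = min(lo, cfg.clamp_low - cfg.grid_pad)
    hi = max(hi, cfg.clamp_high + cfg.grid_pad)
    grid = np.linspace(lo, hi, cfg.grid_points)
    f_dep = _kde_on_grid(dep_scores, grid)
    f_non = _kde_on_grid(non_scores, grid)

    if cfg.fixed_pi is not None:
        pi = float(cfg.fixed_pi)
    else:
        all_scores = scores.to_numpy(float)
        pi = _em_mixing_weight(
            all_scores,
            np.interp(all_scores, grid, f_dep),
            np.interp(all_scores, grid, f_non),
        )

    eps = 1e-300
    raw = pi * f_dep / np.maximum(pi * f_dep + (1.0 - pi) * f_non, eps)
    # order fixed: clamp -> smooth -> re-clip (clamps re-imposed exactly)
    curve = raw.copy()
    curve[grid < cfg.clamp_low] = 1.0
    curve[grid > cfg.clamp_high] = 0.0
    dx = grid[1] - grid[0]
    curve = gaussian_filter1d(curve, sigma=cfg.smooth_sigma / dx, mode="nearest")
    curve = np.clip(curve, 0.0, 1.0)
    curve[grid < cfg.clamp_low] = 1.0
    curve[grid > cfg.clamp_high] = 0.0
    if cfg.enforce_monotone:
        curve = np.minimum.accumulate(curve)
    return DependencyModel(grid=grid, f_dep=f_dep, f_non=f_non, pi=pi, prob_curve=curve, config=cfg)


def dependency_probability(model: DependencyModel, score) -> np.ndarray | float:
    """Probability of dependency at ``score`` (linear interpolation, clamps honored)."""
    cfg = model.config
    score_arr = np.asarray(score, dtype=float)
    prob = np.interp(score_arr, model.grid, model.prob_curve)
    prob = np.where(score_arr < cfg.clamp_low, 1.0, prob)
    prob = np.where(score_arr > cfg.clamp_high, 0.0, prob)
    if np.ndim(score) == 0:
        return float(prob)
    return prob


@dataclass
class DependencyCall:
    gene: str
    score: float
    probability: float
    q: float
    essential: bool


def call_essentials(
    probabilities: pd.Series,
    config: DependencyConfig | None = None,
    scores: pd.Series | None = None,
) -> pd.DataFrame:
    """Rank genes by probability, derive q-values, and flag essentials.

    q at rank i (descending probability) is the mean of (1 - p) over ranks
    1..i; ties in probability share the q of the last tied rank so the result
    is order-independent.  essential <=> p > prob_threshold and q < fdr_threshold.
    """
    cfg = config or DependencyConfig()
    p = probabilities.astype(float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    order = p.sort_values(ascending=False, kind="mergesort")
    q_sorted = np.cumsum(1.0 - order.to_numpy()) / np.arange(1, len(order) + 1)
    q_series = pd.Series(q_sorted, index=order.index)
    # equal probabilities get the (largest) q of their tie group
    tie_max = q_series.groupby(order.to_numpy()).transform("max")
    q = tie_max.reindex(p.index)
    essential = (p > cfg.prob_threshold) & (q < cfg.fdr_threshold)
    out = pd.DataFrame(
        {
            "gene": p.index,
            "score": scores.reindex(p.index).to_numpy() if scores is not None else np.nan,
            "probability": p.to_numpy(),
            "q": q.to_numpy(),
            "essential": essential.to_numpy(),
        }
    ).set_index("gene", drop=False)
    out.index.name = None
    return out


def score_screen(
    counts: CountTable,
    final_samples: list[str],
    reference_samples: list[str],
    pan_essential: set[str],
    unexpressed: set[str],
    config: DependencyConfig | None = None,
) -> tuple[pd.DataFrame, DependencyModel]:
    """End-to-end single-line scoring: guide LFC -> gene score -> mixture -> calls."""
    cfg = config or DependencyConfig()
    if counts.feature_meta is None:
        raise ValueError("count table needs a guide->gene map (feature_meta)")
    lfc = compute_guide_lfc(counts, final_samples, reference_samples, cfg.pseudocount)
    gene_scores = aggregate_gene_scores(lfc, counts.feature_meta)
    model = fit_dependency_model(gene_scores, pan_essential, unexpressed, cfg)
    prob = pd.Series(
        dependency_probability(model, gene_scores.to_numpy()), index=gene_scores.index
    )
    calls = call_essentials(prob, cfg, scores=gene_scores)
    return calls, model
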
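"""ORF rescue-screen scoring.

Each ORF's abundance is normalized to reads per million, log2 transformed,
and compared with the initial (early) time point per biological replicate.
"Rescue ORFs" are those conferring > 1.5 log2-fold enrichment under drug with
q < 0.25.  The screen data carry no replicate-level test the q could come
from, so q-values are derived from a cross-ORF robust null: a robust z-score
against the median/MAD of all per-ORF mean LFCs, an upper-tail normal p, and
Benjamini-Hochberg adjustment.  That construction is a repository convention
and is echoed in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountTable

__all__ = [
    "RescueConfig",
    "OrfLfcTable",
    "ConcordanceResult",
    "compute_orf_lfc",
    "orf_q_values",
    "call_rescue",
    "concordance",
]

MAD_SCALE = 1.4826  # consistency factor for normal data


@dataclass
class RescueConfig:
    lfc_threshold: float = 1.5
    q_threshold: float = 0.25
    pseudocount: float = 1.0
    min_features: int = 20

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be > 0")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must lie in (0, 1)")


@dataclass
class OrfLfcTable:
    """Per-replicate and arm-mean LFCs for one treatment arm."""

    replicate_lfc: pd.DataFrame   # orf x replicate
    mean_lfc: pd.Series           # orf
    arm: str
    n_replicates: int


@dataclass
class ConcordanceResult:
    r_squared: float
    p_value: float
    n: int


def compute_orf_lfc(
    counts: CountTable,
    etp_samples: list[str],
    end_samples: list[str],
    arm: str = "drug",
    pseudocount: float = 1.0,
) -> OrfLfcTable:
    """LFC per replicate: log2(RPM_end + pc) - log2(mean over ETP of RPM + pc)."""
    if not etp_samples:
        raise ValueError("need >= 1 early-time-point sample")
    if not end_samples:
        raise ValueError(f"arm {arm!r} needs >= 1 end-point replicate")
    frame = counts.to_frame()
    for s in etp_samples + end_samples:
        if s not in frame.columns:
            raise KeyError(f"sample {s!r} not in count table")
        if frame[s].sum() == 0:
            raise ValueError(f"sample {s!r} has zero total reads")
    rpm = frame / frame.sum(axis=0) * 1e6
    log = np.log2(rpm + pseudocount)
    etp_ref = log[etp_samples].mean(axis=1)
    rep = log[end_samples].sub(etp_ref, axis=0)
    return OrfLfcTable(
        replicate_lfc=rep,
        mean_lfc=rep.mean(axis=1).rename("mean_lfc"),
        arm=arm,
        n_replicates=len(end_samples),
    )


def orf_q_values(mean_lfc: pd.Series, min_features: int = 20) -> pd.DataFrame:
    """Robust-z / BH q-values from the cross-ORF null of one arm's mean LFCs."""
    x = mean_lfc.astype(float)
    if len(x) < min_features:
        raise ValueError(f"need >= {min_features} ORFs for a stable cross-ORF null")
    med = float(x.median())
    mad = float((x - med).abs().median())
    if mad == 0:
        raise ValueError(
            "MAD of mean LFCs is zero (degenerate arm); add features or replicates"
        )
    z = (x - med) / (MAD_SCALE * mad)
    p = pd.Series(stats.norm.sf(z), index=x.index)
    q = pd.Series(multipletests(p.to_numpy(), method="fdr_bh")[1], index=x.index)
    return pd.DataFrame({"mean_lfc": x, "z": z, "p": p, "q": q})


def call_rescue(
    lfc_table: OrfLfcTable,
    q_values: pd.Series,
    config: RescueConfig | None = None,
    orf_to_gene: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Flag rescue ORFs (LFC and q both pass) and q-only ORFs (q passes alone).

    When ``orf_to_gene`` is given, a gene-level call is added: a gene rescues
    if any of its ORFs does (the best, max-LFC ORF represents the gene).
    """
    cfg = config or RescueConfig()
    q = q_values.reindex(lfc_table.mean_lfc.index)
    if q.isna().any():
        raise ValueError("q-values and LFC table are not aligned by ORF")
    out = pd.DataFrame(
        {
            "orf": lfc_table.mean_lfc.index,
            "mean_lfc": lfc_table.mean_lfc.to_numpy(),
            "q": q.to_numpy(),
        }
    ).set_index("orf", drop=False)
    out.index.name = None
    out["rescue"] = (out["mean_lfc"] > cfg.lfc_threshold) & (out["q"] < cfg.q_threshold)
    out["q_only"] = (out["q"] < cfg.q_threshold) & ~(out["mean_lfc"] > cfg.lfc_threshold)
    if orf_to_gene is not None:
        out["gene"] = [orf_to_gene.get(o, o) for o in out.index]
    else:
        out["gene"] = out.index
    return out


def gene_level_rescue(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse ORF-level calls to genes via the best (max-LFC) ORF; a gene
    rescues if any of its ORFs rescues."""
    best = calls.sort_values("mean_lfc", ascending=False).drop_duplicates("gene")
    agg = calls.groupby("gene").agg(rescue=("rescue", "any"), q_only=("q_only", "any"))
    best = best.set_index("gene")[["orf", "mean_lfc", "q"]]
    return best.join(agg).sort_index()


def concordance(lfc_a: pd.Series, lfc_b: pd.Series) -> ConcordanceResult:
    """R^2 (OLS of B on A) between two arms' per-ORF LFCs, with slope p-value."""
    shared = lfc_a.index.intersection(lfc_b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared ORFs")
    a = lfc_a.loc[shared].to_numpy(float)
    b = lfc_b.loc[shared].to_numpy(float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in an LFC vector")
    res = stats.linregress(a, b)
    return ConcordanceResult(
        r_squared=float(res.rvalue**2), p_value=float(res.pvalue), n=len(shared)
    )
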
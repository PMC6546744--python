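"""Clonal DNA-barcode selection analysis.

Cells are tagged with heritable DNA barcodes before being split into
replicate drug / vehicle treatments; if drug tolerance is predetermined, the
same barcodes survive drug in every replicate.  The analysis filters barcodes
on an early-time-point (ETP) read minimum, computes the fraction of eligible
barcodes surviving drug, and profiles how many treated replicates each
surviving barcode is shared with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountTable

__all__ = [
    "BarcodeConfig",
    "SharingSummary",
    "filter_etp",
    "surviving_fraction",
    "sharing_profile",
]


@dataclass
class BarcodeConfig:
    min_etp_count: int = 3
    detection_threshold: int = 1
    # denominator convention for the surviving fraction: "union" counts
    # eligible barcodes detected in >=1 sample of any condition; "eligible"
    # uses every ETP-passing barcode.
    denominator: str = "union"

    def __post_init__(self) -> None:
        if self.min_etp_count < 1:
            raise ValueError("min_etp_count must be >= 1")
        if self.detection_threshold < 1:
            raise ValueError("detection_threshold must be >= 1")
        if self.denominator not in {"union", "eligible"}:
            raise ValueError("denominator must be 'union' or 'eligible'")


@dataclass
class SharingSummary:
    surviving_percent: float                    # % of denominator barcodes in >=1 treated replicate
    shared_across_all_percent: float            # % of survivors present in all treated replicates
    per_replicate_sharing: dict[str, dict[int, int]]  # replicate -> {j other replicates: count}
    n_survivors: int
    n_eligible: int
    treated_only_percent: float = float("nan")  # % of survivors absent from every vehicle replicate
    denominator: str = "union"
    extras: dict = field(default_factory=dict)


def filter_etp(table: CountTable, etp_sample: str, config: BarcodeConfig | None = None) -> set[str]:
    """Barcodes with ETP read count >= min_etp_count (boundary inclusive)."""
    cfg = config or BarcodeConfig()
    if etp_sample not in table.sample_ids:
        raise KeyError(f"ETP sample {etp_sample!r} missing from barcode table")
    col = table.column(etp_sample)
    return {f for f, c in zip(table.feature_ids, col) if c >= cfg.min_etp_count}


def _detected(table: CountTable, samples: list[str], threshold: int) -> pd.DataFrame:
    frame = table.to_frame()
    return frame[samples] >= threshold


def surviving_fraction(
    table: CountTable,
    eligible: set[str],
    treated_samples: list[str],
    config: BarcodeConfig | None = None,
    all_samples: list[str] | None = None,
) -> float:
    """Percentage of barcodes present (>= detection threshold) in >= 1 treated sample.

    Under the default "union" denominator convention, the denominator is the
    set of eligible barcodes detected in >= 1 sample of any condition
    (``all_samples``, defaulting to every non-ETP column).
    """
    cfg = config or BarcodeConfig()
    if not treated_samples:
        raise ValueError("need >= 1 treated sample")
    if not eligible:
        raise ValueError("eligible barcode set is empty")
    frame = table.to_frame()
    elig_idx = frame.index.isin(eligible)
    if cfg.denominator == "union":
        pool = all_samples if all_samples is not None else treated_samples
        seen = (frame.loc[elig_idx, pool] >= cfg.detection_threshold).any(axis=1)
        denom = int(seen.sum())
    else:
        denom = int(elig_idx.sum())
    if denom == 0:
        raise ValueError("denominator barcode set is empty")
    survived = (frame.loc[elig_idx, treated_samples] >= cfg.detection_threshold).any(axis=1)
    return 100.0 * float(survived.sum()) / denom


def sharing_profile(
    table: CountTable,
    eligible: set[str],
    treated_samples: list[str],
    vehicle_samples: list[str] | None = None,
    config: BarcodeConfig | None = None,
) -> SharingSummary:
    """Cross-replicate sharing of surviving barcodes.

    For each treated replicate, counts its barcodes by the number *j* of
    other treated replicates also containing them; reports the fraction of
    survivors present in all treated replicates and (when vehicle samples are
    given) the fraction of survivors absent from every vehicle replicate.
    """
    cfg = config or BarcodeConfig()
    if len(treated_samples) < 2:
        raise ValueError("sharing profile needs >= 2 treated replicates")
    frame = table.to_frame()
    elig = frame.loc[frame.index.isin(eligible)]
    det = elig[treated_samples] >= cfg.detection_threshold
    n_present = det.sum(axis=1)
    survivors = n_present >= 1
    n_survivors = int(survivors.sum())

    per_rep: dict[str, dict[int, int]] = {}
    r = len(treated_samples)
    for rep in treated_samples:
        present = det[rep]
        others = (n_present[present] - 1).astype(int)
        counts = others.value_counts().to_dict()
        per_rep[rep] = {j: int(counts.get(j, 0)) for j in range(r)}

    if n_survivors:
        shared_all = 100.0 * float((n_present == r).sum()) / n_survivors
    else:
        shared_all = 0.0

    treated_only = float("nan")
    if vehicle_samples:
        veh_det = (elig[vehicle_samples] >= cfg.detection_threshold).any(axis=1)
        if n_survivors:
            treated_only = 100.0 * float((survivors & ~veh_det).sum()) / n_survivors
        else:
            treated_only = 0.0

    all_cond = treated_samples + (vehicle_samples or [])
    surv_pct = surviving_fraction(table, eligible, treated_samples, cfg, all_samples=all_cond)
    return SharingSummary(
        surviving_percent=surv_pct,
        shared_across_all_percent=shared_all,
        per_replicate_sharing=per_rep,
        n_survivors=n_survivors,
        n_eligible=len(elig),
        treated_only_percent=treated_only,
        denominator=cfg.denominator,
    )
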
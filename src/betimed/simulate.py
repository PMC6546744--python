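"""Synthetic screen, expression, barcode, coverage and dose-response generators.

Every generator is deterministic given its seed and returns, alongside the
simulated data, a :class:`TruthTables` record of what was planted so that
downstream callers can be scored against ground truth.

Count-bearing assays (CRISPR, ORF, barcodes) share one sampling model:
clone abundances are log-normally skewed, planted effects act multiplicatively
on final-time-point abundance (log2 fold changes), the final pool is
renormalized (clones compete for sequencing depth), and reads are drawn from
a negative binomial with a common dispersion - the screen-literature standard
count model.  Scaled default shapes (1,000 genes, 10,000 barcodes) let the
whole pipeline run in minutes; the full library geometry (73,687 guides /
18,454 genes, ~17,255 ORFs / 12,579 genes, 600,000 barcodes) is available by
overriding the size fields.

Default rates mirror the study conditions where those are stated: 4 guides
per gene with ~1,000 non-targeting controls (scaled to 100), a ~13% essential
fraction (2455 of 18,454 called genes), an ~8.7% pan-essential anchor
fraction (1607 of 18,454), a ~28% drug-suppressed fraction (5241 genes),
8 barcode replicates with a 2% predetermined-tolerant clone fraction and a
0.967 per-replicate kill probability for the rest (back-solved from the 25%
surviving / 8% shared-across-all clone-tracing readout).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CountTable, IntervalSet

__all__ = [
    "TruthTables",
    "CrisprSimConfig",
    "OrfSimConfig",
    "ExpressionSimConfig",
    "BarcodeSimConfig",
    "DoseResponseSimConfig",
    "ChipSimConfig",
    "StudyConfig",
    "simulate_crispr_screen",
    "simulate_orf_screen",
    "simulate_expression",
    "simulate_barcode_experiment",
    "simulate_dose_response",
    "simulate_chip_reads",
    "simulate_study",
]


@dataclass
class TruthTables:
    """Planted ground truth accompanying each simulated dataset."""

    essential_genes: set[str] = field(default_factory=set)
    pan_essential_anchor: set[str] = field(default_factory=set)
    unexpressed_genes: set[str] = field(default_factory=set)
    suppressed_genes: set[str] = field(default_factory=set)
    rescue_genes: set[str] = field(default_factory=set)
    rescue_orfs: set[str] = field(default_factory=set)
    tolerant_barcodes: set[str] = field(default_factory=set)
    chip_enriched_genes: set[str] = field(default_factory=set)
    mediators: set[str] = field(default_factory=set)
    gene_universe: list[str] = field(default_factory=list)
    true_excess: pd.DataFrame | None = None


def gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2 (Poisson at dispersion 0)."""
    mean = np.clip(np.asarray(mean, dtype=float), 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _lognormal_abundance(rng: np.random.Generator, n: int, sigma: float = 0.5) -> np.ndarray:
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return raw / raw.sum()


# ---------------------------------------------------------------------------
# CRISPR knockout screen


@dataclass
class CrisprSimConfig:
    n_genes: int = 1000
    guides_per_gene: int = 4
    n_control_guides: int = 100
    n_samples_per_arm: int = 3          # early-time-point and final replicates
    mean_reads_per_guide: float = 500.0
    dispersion: float = 0.2
    fraction_essential: float = 0.13
    essential_effect: float = -1.0      # mean guide LFC of a planted essential gene
    guide_efficacy_sd: float = 0.1
    pan_anchor_fraction: float = 0.087  # essential genes flagged as known pan-essentials
    unexpressed_fraction: float = 0.25  # non-essential genes flagged unexpressed
    abundance_sigma: float = 0.5
    max_library: int = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_essential", "pan_anchor_fraction", "unexpressed_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not np.isfinite(self.essential_effect):
            raise ValueError("essential_effect must be finite")


def simulate_crispr_screen(
    config: CrisprSimConfig | None = None,
    effect_override: dict[str, float] | None = None,
    essential_genes: set[str] | None = None,
    pan_anchor_genes: set[str] | None = None,
    unexpressed_genes: set[str] | None = None,
    gene_ids: list[str] | None = None,
) -> tuple[CountTable, TruthTables]:
    """Two-time-point depletion screen with planted essential genes.

    By default the essential set, the pan-essential anchor subset and the
    unexpressed set are drawn at the configured fractions; passing any of
    them explicitly replaces the corresponding draw (the explicit set is used
    exactly as given).  ``effect_override`` assigns per-gene depletion
    effects on top of the default ``essential_effect``.  Non-targeting
    control guides never carry a planted effect.
    """
    cfg = config or CrisprSimConfig()
    n_guides = cfg.n_genes * cfg.guides_per_gene + cfg.n_control_guides
    if n_guides > cfg.max_library:
        raise ValueError(f"library of {n_guides} guides exceeds representable maximum")
    rng = np.random.default_rng(cfg.seed)
    genes = gene_ids if gene_ids is not None else gene_names(cfg.n_genes)
    if len(genes) != cfg.n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    if essential_genes is not None:
        essential = set(essential_genes)
    else:
        n_ess = int(round(cfg.fraction_essential * cfg.n_genes))
        essential = set(rng.choice(genes, size=n_ess, replace=False))
    if pan_anchor_genes is not None:
        pan_anchor = set(pan_anchor_genes)
    else:
        n_anchor = int(round(cfg.pan_anchor_fraction * cfg.n_genes))
        anchor_pool = sorted(essential - set(effect_override or ()))
        pan_anchor = set(
            rng.choice(anchor_pool, size=min(n_anchor, len(anchor_pool)), replace=False)
        )
    if unexpressed_genes is not None:
        unexpressed = set(unexpressed_genes)
    else:
        non_essential = sorted(set(genes) - essential)
        n_unexpr = int(round(cfg.unexpressed_fraction * cfg.n_genes))
        unexpressed = set(
            rng.choice(non_essential, size=min(n_unexpr, len(non_essential)), replace=False)
        )

    effects = {g: 0.0 for g in genes}
    for g in essential:
        effects[g] = cfg.essential_effect
    if effect_override:
        effects.update(effect_override)

    guide_ids, guide_lfc, meta = [], [], {}
    for g in genes:
        for j in range(cfg.guides_per_gene):
            gid = f"{g}_sg{j + 1}"
            efficacy = max(rng.normal(1.0, cfg.guide_efficacy_sd), 0.0)
            guide_ids.append(gid)
            guide_lfc.append(effects[g] * efficacy)
            meta[gid] = (g, False)
    for j in range(cfg.n_control_guides):
        gid = f"CTRL_{j + 1:04d}"
        guide_ids.append(gid)
        guide_lfc.append(0.0)
        meta[gid] = ("NONTARGETING", True)
    lfc = np.asarray(guide_lfc)

    abundance = _lognormal_abundance(rng, n_guides, cfg.abundance_sigma)
    depth = cfg.mean_reads_per_guide * n_guides
    final_rel = abundance * np.exp2(lfc)
    final_rel = final_rel / final_rel.sum()

    samples, columns = [], []
    for i in range(cfg.n_samples_per_arm):
        samples.append(f"ETP_{i + 1}")
        columns.append(_nb_counts(rng, depth * abundance, cfg.dispersion))
    for i in range(cfg.n_samples_per_arm):
        samples.append(f"FINAL_{i + 1}")
        columns.append(_nb_counts(rng, depth * final_rel, cfg.dispersion))

    table = CountTable(guide_ids, samples, np.column_stack(columns), feature_meta=meta)
    truth = TruthTables(
        essential_genes=essential,
        pan_essential_anchor=pan_anchor,
        unexpressed_genes=unexpressed,
        gene_universe=genes,
    )
    return table, truth


# ---------------------------------------------------------------------------
# ORF rescue screen


@dataclass
class OrfSimConfig:
    n_orfs: int = 1000                  # one ORF per gene at the scaled default
    n_etp_samples: int = 2
    n_replicates_per_arm: int = 2
    mean_reads_per_orf: float = 500.0
    dispersion: float = 0.05
    fraction_rescue: float = 0.02
    rescue_effect: float = 2.0          # mean LFC under drug for planted rescue ORFs
    drift_sd: float = 0.15              # drug-independent per-ORF drift (all final arms)
    arm_noise_sd: float = 0.1           # per-arm noise on the planted drug effect
    abundance_sigma: float = 0.5
    max_library: int = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_rescue <= 1:
            raise ValueError("fraction_rescue must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def simulate_orf_screen(
    config: OrfSimConfig | None = None,
    effect_override: dict[str, float] | None = None,
    rescue_genes: set[str] | None = None,
    gene_ids: list[str] | None = None,
) -> tuple[CountTable, TruthTables]:
    """ORF screen: ETP samples, a vehicle arm, and two drug arms (JQ1/IBET151-like).

    Planted rescue ORFs are enriched in the drug arms only; the two drug arms
    share the planted effect and the drug-independent drift, with independent
    per-arm noise on top.  An explicit ``rescue_genes`` set replaces the
    random draw.
    """
    cfg = config or OrfSimConfig()
    if cfg.n_orfs > cfg.max_library:
        raise ValueError("ORF library exceeds representable maximum")
    rng = np.random.default_rng(cfg.seed)
    genes = gene_ids if gene_ids is not None else gene_names(cfg.n_orfs)
    if len(genes) != cfg.n_orfs:
        raise ValueError("gene_ids length must equal n_orfs")
    orfs = [f"ORF_{g}" for g in genes]
    orf_gene = dict(zip(orfs, genes))

    if rescue_genes is not None:
        rescue = set(rescue_genes)
    else:
        n_rescue = int(round(cfg.fraction_rescue * cfg.n_orfs))
        rescue = set(rng.choice(genes, size=n_rescue, replace=False))
    effects = {g: (cfg.rescue_effect if g in rescue else 0.0) for g in genes}
    if effect_override:
        effects.update(effect_override)

    base_effect = np.asarray([effects[g] for g in genes])
    drift = rng.normal(0.0, cfg.drift_sd, size=cfg.n_orfs)
    arm_lfc = {
        "DMSO": drift,
        "JQ1": drift + base_effect + rng.normal(0.0, cfg.arm_noise_sd, size=cfg.n_orfs),
        "IBET151": drift + base_effect + rng.normal(0.0, cfg.arm_noise_sd, size=cfg.n_orfs),
    }

    abundance = _lognormal_abundance(rng, cfg.n_orfs, cfg.abundance_sigma)
    depth = cfg.mean_reads_per_orf * cfg.n_orfs
    samples, columns = [], []
    for r in range(cfg.n_etp_samples):
        samples.append(f"ETP_{r + 1}")
        columns.append(_nb_counts(rng, depth * abundance, cfg.dispersion))
    for arm, lfc in arm_lfc.items():
        rel = abundance * np.exp2(lfc)
        rel = rel / rel.sum()
        for r in range(cfg.n_replicates_per_arm):
            samples.append(f"{arm}_{r + 1}")
            columns.append(_nb_counts(rng, depth * rel, cfg.dispersion))

    meta = {o: (g, False) for o, g in orf_gene.items()}
    table = CountTable(orfs, samples, np.column_stack(columns), feature_meta=meta)
    truth = TruthTables(
        rescue_genes=rescue,
        rescue_orfs={f"ORF_{g}" for g in rescue},
        gene_universe=list(genes),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Expression profiles


@dataclass
class ExpressionSimConfig:
    n_genes: int = 1000
    n_reps: int = 5                     # replicates per condition
    fraction_suppressed: float = 0.28
    effect: float = 1.5                 # log2 down-shift under drug (3 x noise_sd default)
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    unexpressed_level: float = 0.05     # log2 level of designated unexpressed genes
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_suppressed <= 1:
            raise ValueError("fraction_suppressed must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def simulate_expression(
    config: ExpressionSimConfig | None = None,
    effect_override: dict[str, float] | None = None,
    suppressed_genes: set[str] | None = None,
    unexpressed_genes: set[str] | None = None,
    gene_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, TruthTables]:
    """Gaussian log2 expression, vehicle vs drug, with planted suppressed genes.

    Designated unexpressed genes sit near zero in both conditions (so the
    dependency stage can recover them with its expression cutoff) and are
    never planted as suppressed.  An explicit ``suppressed_genes`` set
    replaces the random draw.
    """
    cfg = config or ExpressionSimConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = gene_ids if gene_ids is not None else gene_names(cfg.n_genes)
    if len(genes) != cfg.n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    unexpressed = set(unexpressed_genes or ())

    if suppressed_genes is not None:
        suppressed = set(suppressed_genes) - unexpressed
    else:
        eligible = [g for g in genes if g not in unexpressed]
        n_sup = int(round(cfg.fraction_suppressed * cfg.n_genes))
        suppressed = set(rng.choice(eligible, size=min(n_sup, len(eligible)), replace=False))
    effects = {g: (cfg.effect if g in suppressed else 0.0) for g in genes}
    if effect_override:
        effects.update({g: e for g, e in effect_override.items() if g not in unexpressed})

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    is_unexpr = np.asarray([g in unexpressed for g in genes])
    baseline = np.where(is_unexpr, cfg.unexpressed_level, np.maximum(baseline, 1.0))
    shift = np.asarray([effects[g] for g in genes])
    shift = np.where(is_unexpr, 0.0, shift)
    # unexpressed transcripts sit at the detection floor with floor-level noise
    gene_sd = np.where(is_unexpr, min(cfg.noise_sd, 0.03), cfg.noise_sd)

    cols, names = [], []
    for r in range(cfg.n_reps):
        names.append(f"vehicle_{r + 1}")
        cols.append(baseline + rng.normal(0.0, 1.0, size=cfg.n_genes) * gene_sd)
    for r in range(cfg.n_reps):
        names.append(f"drug_{r + 1}")
        cols.append(baseline - shift + rng.normal(0.0, 1.0, size=cfg.n_genes) * gene_sd)
    matrix = pd.DataFrame(np.column_stack(cols), index=genes, columns=names)
    matrix[matrix < 0] = 0.0
    truth = TruthTables(
        suppressed_genes=suppressed,
        unexpressed_genes=unexpressed,
        gene_universe=list(genes),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Clonal barcode experiment


@dataclass
class BarcodeSimConfig:
    n_barcodes: int = 10_000
    n_replicates: int = 8
    fraction_tolerant: float = 0.02
    kill_probability: float = 0.967     # per treated replicate, non-tolerant clones
    reads_per_sample: float = 1e6
    dispersion: float = 0.2
    abundance_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_tolerant", "kill_probability"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def simulate_barcode_experiment(
    config: BarcodeSimConfig | None = None,
) -> tuple[CountTable, TruthTables]:
    """Clone-tracing experiment: one ETP, replicate drug and vehicle samples.

    All samples derive from the same pre-treatment clone pool.  Predetermined
    tolerant clones survive drug in every replicate; the rest survive each
    drug replicate independently with probability 1 - kill_probability.
    Vehicle replicates retain every clone.
    """
    cfg = config or BarcodeSimConfig()
    rng = np.random.default_rng(cfg.seed)
    barcodes = [f"BC{i:06d}" for i in range(1, cfg.n_barcodes + 1)]
    tolerant_mask = rng.random(cfg.n_barcodes) < cfg.fraction_tolerant
    abundance = _lognormal_abundance(rng, cfg.n_barcodes, cfg.abundance_sigma)

    samples = ["ETP"]
    columns = [_nb_counts(rng, cfg.reads_per_sample * abundance, cfg.dispersion)]
    for r in range(cfg.n_replicates):
        survive = tolerant_mask | (rng.random(cfg.n_barcodes) >= cfg.kill_probability)
        rel = abundance * survive
        total = rel.sum()
        rel = rel / total if total > 0 else rel
        samples.append(f"JQ1_{r + 1}")
        columns.append(_nb_counts(rng, cfg.reads_per_sample * rel, cfg.dispersion))
    for r in range(cfg.n_replicates):
        samples.append(f"DMSO_{r + 1}")
        columns.append(_nb_counts(rng, cfg.reads_per_sample * abundance, cfg.dispersion))

    table = CountTable(barcodes, samples, np.column_stack(columns))
    truth = TruthTables(tolerant_barcodes={b for b, t in zip(barcodes, tolerant_mask) if t})
    return table, truth


# ---------------------------------------------------------------------------
# Dose-response surfaces


@dataclass
class DoseResponseSimConfig:
    doses_a: tuple = (0.0, 0.0625, 0.125, 0.25, 0.5, 1.0, 2.0)
    doses_b: tuple = (0.0, 0.0625, 0.125, 0.25, 0.5, 1.0, 2.0)
    ec50_a: float = 0.5
    hill_a: float = 1.5
    ec50_b: float = 0.5
    hill_b: float = 1.5
    synergy_excess: float = 0.0         # extra inhibition planted in every combo well
    noise_sd: float = 0.0
    seed: int = 0


def _hill_survival(dose: np.ndarray, ec50: float, hill: float) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / ec50) ** hill, 0.0)
    return 1.0 / (1.0 + ratio)


def simulate_dose_response(
    config: DoseResponseSimConfig | None = None,
) -> tuple[pd.DataFrame, TruthTables]:
    """Viability = product of single-agent Hill survivals minus planted excess.

    The planted excess applies only where both doses are nonzero; noise is
    additive Gaussian; the surface is clipped to [0, 1].
    """
    cfg = config or DoseResponseSimConfig()
    rng = np.random.default_rng(cfg.seed)
    sa = _hill_survival(np.asarray(cfg.doses_a), cfg.ec50_a, cfg.hill_a)
    sb = _hill_survival(np.asarray(cfg.doses_b), cfg.ec50_b, cfg.hill_b)
    surface = sa[:, None] * sb[None, :]
    excess = np.zeros_like(surface)
    combo = (np.asarray(cfg.doses_a)[:, None] > 0) & (np.asarray(cfg.doses_b)[None, :] > 0)
    excess[combo] = cfg.synergy_excess
    viability = surface - excess
    if cfg.noise_sd > 0:
        viability = viability + rng.normal(0.0, cfg.noise_sd, size=surface.shape)
    viability = np.clip(viability, 0.0, 1.0)
    viability[0, 0] = 1.0
    frame = pd.DataFrame(viability, index=list(cfg.doses_a), columns=list(cfg.doses_b))
    truth = TruthTables(
        true_excess=pd.DataFrame(excess, index=list(cfg.doses_a), columns=list(cfg.doses_b))
    )
    return frame, truth


# ---------------------------------------------------------------------------
# ChIP read intervals


@dataclass
class ChipSimConfig:
    n_genes: int = 200
    gene_length: int = 10_000
    gene_spacing: int = 1_500_000       # keeps +-500 kb flanked windows disjoint
    base_reads_per_gene: float = 30.0
    enrichment_fold: float = 3.0
    read_length: int = 50
    seed: int = 0


def simulate_chip_reads(
    config: ChipSimConfig | None = None,
    enriched_genes: set[str] | None = None,
    gene_ids: list[str] | None = None,
) -> tuple[IntervalSet, IntervalSet, TruthTables]:
    """Gene intervals on one synthetic chromosome plus aligned-read intervals.

    Reads fall uniformly within their gene's body; genes in ``enriched_genes``
    receive ``enrichment_fold`` times the base expected read count.

    Returns (genes, reads, truth).
    """
    cfg = config or ChipSimConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = gene_ids if gene_ids is not None else gene_names(cfg.n_genes)
    if len(genes) != cfg.n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    enriched = set(enriched_genes or ())

    gene_rows, read_rows = [], []
    for i, g in enumerate(genes):
        start = 1_000_000 + i * cfg.gene_spacing
        end = start + cfg.gene_length
        gene_rows.append(("chrS", start, end, g, "+"))
        mean_reads = cfg.base_reads_per_gene * (cfg.enrichment_fold if g in enriched else 1.0)
        n_reads = rng.poisson(mean_reads)
        positions = rng.integers(start, end - cfg.read_length, size=n_reads)
        strands = rng.choice(["+", "-"], size=n_reads)
        for p, s in zip(positions, strands):
            read_rows.append(("chrS", int(p), int(p) + cfg.read_length, "read", s))
    gene_set = IntervalSet.from_tuples(gene_rows)
    read_set = IntervalSet.from_tuples(read_rows)
    truth = TruthTables(chip_enriched_genes=enriched, gene_universe=list(genes))
    return gene_set, read_set, truth


# ---------------------------------------------------------------------------
# Combined study scenario (all assays over one gene universe)


@dataclass
class StudyConfig:
    """One coherent synthetic study: CRISPR + ORF + expression share a universe.

    Planted mediator genes sit in all three truth sets with effects above each
    assay's detection margin (mediators are, by construction, the strong hits
    every assay agrees on); the remaining planted members of each set carry
    that assay's default effect.
    """

    n_genes: int = 1000
    n_mediators: int = 8
    mediator_depletion: float = -1.8
    mediator_suppression: float = 2.0   # 4 x expression noise sd
    mediator_rescue: float = 3.0
    crispr: CrisprSimConfig = field(default_factory=CrisprSimConfig)
    orf: OrfSimConfig = field(default_factory=OrfSimConfig)
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)
    barcodes: BarcodeSimConfig = field(default_factory=BarcodeSimConfig)
    dose_response: DoseResponseSimConfig = field(
        default_factory=lambda: DoseResponseSimConfig(synergy_excess=0.15, noise_sd=0.01)
    )
    chip: ChipSimConfig = field(default_factory=ChipSimConfig)
    seed: int = 0


@dataclass
class StudyData:
    crispr_counts: CountTable
    orf_counts: CountTable
    expression: pd.DataFrame
    barcode_counts: CountTable
    dose_matrix: pd.DataFrame
    chip_genes: IntervalSet
    chip_reads: IntervalSet
    truth: TruthTables


def simulate_study(config: StudyConfig | None = None) -> StudyData:
    cfg = config or StudyConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = gene_names(cfg.n_genes)
    gene_arr = np.asarray(genes)
    mediators = set(rng.choice(gene_arr, size=cfg.n_mediators, replace=False))
    sub_seeds = rng.integers(0, 2**31 - 1, size=6)

    # Plant the per-assay sets so that the three-way truth intersection is
    # exactly the designated mediators: pairwise overlaps (e.g. suppressed
    # and essential) remain, but no non-mediator gene sits in all three sets.
    def draw(pool: set[str], n: int) -> set[str]:
        pool_arr = np.asarray(sorted(pool))
        return set(rng.choice(pool_arr, size=min(n, len(pool_arr)), replace=False))

    non_med = set(genes) - mediators
    n_ess = int(round(cfg.crispr.fraction_essential * cfg.n_genes))
    essential = mediators | draw(non_med, max(n_ess - cfg.n_mediators, 0))
    pan_anchor = draw(essential - mediators,
                      int(round(cfg.crispr.pan_anchor_fraction * cfg.n_genes)))
    unexpressed = draw(non_med - essential,
                       int(round(cfg.crispr.unexpressed_fraction * cfg.n_genes)))
    n_sup = int(round(cfg.expression.fraction_suppressed * cfg.n_genes))
    suppressed = mediators | draw(non_med - unexpressed, max(n_sup - cfg.n_mediators, 0))
    n_resc = int(round(cfg.orf.fraction_rescue * cfg.n_genes))
    rescue_pool = non_med - essential - suppressed
    rescue = mediators | draw(rescue_pool, max(n_resc - cfg.n_mediators, 0))

    crispr_cfg = replace(cfg.crispr, n_genes=cfg.n_genes, seed=int(sub_seeds[0]))
    crispr_counts, crispr_truth = simulate_crispr_screen(
        crispr_cfg,
        essential_genes=essential,
        pan_anchor_genes=pan_anchor,
        unexpressed_genes=unexpressed,
        effect_override={g: cfg.mediator_depletion for g in mediators},
        gene_ids=genes,
    )

    expr_cfg = replace(cfg.expression, n_genes=cfg.n_genes, seed=int(sub_seeds[1]))
    expression, expr_truth = simulate_expression(
        expr_cfg,
        suppressed_genes=suppressed,
        effect_override={g: cfg.mediator_suppression for g in mediators},
        unexpressed_genes=unexpressed,
        gene_ids=genes,
    )

    orf_cfg = replace(cfg.orf, n_orfs=cfg.n_genes, seed=int(sub_seeds[2]))
    orf_counts, orf_truth = simulate_orf_screen(
        orf_cfg,
        rescue_genes=rescue,
        effect_override={g: cfg.mediator_rescue for g in mediators},
        gene_ids=genes,
    )

    barcode_counts, bc_truth = simulate_barcode_experiment(
        replace(cfg.barcodes, seed=int(sub_seeds[3]))
    )
    dose_matrix, dose_truth = simulate_dose_response(
        replace(cfg.dose_response, seed=int(sub_seeds[4]))
    )
    chip_cfg = replace(cfg.chip, seed=int(sub_seeds[5]))
    chip_gene_ids = genes[: chip_cfg.n_genes]
    chip_genes, chip_reads, chip_truth = simulate_chip_reads(
        chip_cfg,
        enriched_genes=orf_truth.rescue_genes & set(chip_gene_ids),
        gene_ids=chip_gene_ids,
    )

    truth = TruthTables(
        essential_genes=crispr_truth.essential_genes,
        pan_essential_anchor=crispr_truth.pan_essential_anchor,
        unexpressed_genes=crispr_truth.unexpressed_genes,
        suppressed_genes=expr_truth.suppressed_genes,
        rescue_genes=orf_truth.rescue_genes,
        rescue_orfs=orf_truth.rescue_orfs,
        tolerant_barcodes=bc_truth.tolerant_barcodes,
        chip_enriched_genes=chip_truth.chip_enriched_genes,
        mediators=mediators,
        gene_universe=genes,
        true_excess=dose_truth.true_excess,
    )
    return StudyData(
        crispr_counts=crispr_counts,
        orf_counts=orf_counts,
        expression=expression,
        barcode_counts=barcode_counts,
        dose_matrix=dose_matrix,
        chip_genes=chip_genes,
        chip_reads=chip_reads,
        truth=truth,
    )
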
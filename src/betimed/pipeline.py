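"""Stage orchestration: one config + seed -> a directory of stage outputs.

``run_pipeline`` wires the stages together: simulate (or load) inputs, score
the CRISPR screen through the dependency mixture model, score the ORF rescue
screen, call drug-suppressed genes, intersect the three evidence layers into
mediator nominations, and run the auxiliary quantifications (ChIP binding
scores, barcode sharing, Bliss synergy).  Outputs are plain TSV/JSON plus a
provenance record echoing every threshold and the seed; identical config and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import barcodes as bc
from . import chip as chipmod
from .dependency import DependencyConfig, score_screen
from .integrate import classify_genes, overlap_chisq, overlap_fisher
from .io import (
    CountTable,
    read_bedgraph,
    read_count_table,
    read_intervals,
    write_count_table,
    write_intervals,
)
from .markers import MarkerConfig, run_marker_selection, suppressed_set
from .rescue import RescueConfig, call_rescue, compute_orf_lfc, concordance, gene_level_rescue, orf_q_values
from .simulate import StudyConfig, StudyData, simulate_study
from .synergy import DoseMatrix, bliss_excess

__all__ = ["RunConfig", "ConfigurationError", "run_pipeline", "load_config"]

ALL_STAGES = (
    "simulate",
    "crispr-dep",
    "orf-rescue",
    "de",
    "integrate",
    "chip-score",
    "barcodes",
    "synergy",
)


class ConfigurationError(ValueError):
    """Raised before any computation when a requested stage lacks its inputs."""


@dataclass
class RunConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    stages: tuple = ALL_STAGES
    inputs: dict = field(default_factory=dict)   # real-input paths; empty => simulate
    study: StudyConfig = field(default_factory=StudyConfig)
    dependency: DependencyConfig = field(default_factory=DependencyConfig)
    rescue: RescueConfig = field(default_factory=RescueConfig)
    marker: MarkerConfig = field(default_factory=MarkerConfig)
    barcode: bc.BarcodeConfig = field(default_factory=bc.BarcodeConfig)
    chip: chipmod.ChipConfig = field(default_factory=chipmod.ChipConfig)
    bliss_min_excess: float = 0.05


_STAGE_INPUTS = {
    "crispr-dep": ["crispr_counts", "guide_map", "pan_essential", "expression"],
    "orf-rescue": ["orf_counts", "orf_map"],
    "de": ["expression", "expression_labels"],
    "chip-score": ["genes_bed", "reads_bed"],
    "barcodes": ["barcode_counts"],
    "synergy": ["dose_matrix"],
}
_STAGE_DEPS = {"integrate": ["crispr-dep", "orf-rescue", "de"]}


def _validate(config: RunConfig) -> None:
    stages = list(config.stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
    simulated = "simulate" in stages
    for stage in stages:
        for dep in _STAGE_DEPS.get(stage, []):
            if dep not in stages:
                raise ConfigurationError(f"stage {stage!r} requires stage {dep!r}")
        if not simulated:
            missing = [k for k in _STAGE_INPUTS.get(stage, []) if k not in config.inputs]
            if missing:
                raise ConfigurationError(
                    f"stage {stage!r} requested without inputs {missing} "
                    "(and no simulate stage)"
                )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _write_gene_set(genes: set[str], path: Path) -> None:
    path.write_text("".join(f"{g}\n" for g in sorted(genes)))


def _read_gene_set(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def _write_study_inputs(data: StudyData, outdir: Path) -> None:
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    write_count_table(data.crispr_counts, inputs / "crispr_counts.tsv", inputs / "guide_map.tsv")
    write_count_table(data.orf_counts, inputs / "orf_counts.tsv", inputs / "orf_map.tsv")
    data.expression.rename_axis("gene").to_csv(inputs / "expression.tsv", sep="\t")
    write_count_table(data.barcode_counts, inputs / "barcode_counts.tsv")
    data.dose_matrix.rename_axis("dose_a").to_csv(inputs / "dose_matrix.csv")
    write_intervals(data.chip_genes, inputs / "genes.bed")
    write_intervals(data.chip_reads, inputs / "reads.bed")
    _write_gene_set(data.truth.pan_essential_anchor, inputs / "pan_essential_reference.txt")
    labels = ["vehicle" if c.startswith("vehicle") else "drug" for c in data.expression.columns]
    (inputs / "expression_labels.tsv").write_text(
        "sample\tgroup\n"
        + "".join(f"{c}\t{g}\n" for c, g in zip(data.expression.columns, labels))
    )
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    t = data.truth
    for name, s in (
        ("essential", t.essential_genes),
        ("pan_essential_anchor", t.pan_essential_anchor),
        ("unexpressed", t.unexpressed_genes),
        ("suppressed", t.suppressed_genes),
        ("rescue_genes", t.rescue_genes),
        ("tolerant_barcodes", t.tolerant_barcodes),
        ("mediators", t.mediators),
    ):
        _write_gene_set(s, truth_dir / f"truth_{name}.tsv")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns a dict of in-memory stage results."""
    _validate(config)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # ----- inputs: simulate or load ---------------------------------------
    if "simulate" in config.stages:
        study_cfg = replace(config.study, seed=config.seed)
        data = simulate_study(study_cfg)
        _write_study_inputs(data, outdir)
        results["truth"] = data.truth
        crispr_counts, orf_counts = data.crispr_counts, data.orf_counts
        expression, barcode_counts = data.expression, data.barcode_counts
        dose_matrix = data.dose_matrix
        chip_genes, chip_reads = data.chip_genes, data.chip_reads
        pan_essential = data.truth.pan_essential_anchor
        label_groups = pd.Series(
            ["vehicle" if c.startswith("vehicle") else "drug" for c in expression.columns],
            index=expression.columns,
        )
    else:
        paths = config.inputs
        crispr_counts = orf_counts = barcode_counts = None
        expression = dose_matrix = None
        chip_genes = chip_reads = None
        pan_essential = None
        label_groups = None
        if "crispr-dep" in config.stages or "orf-rescue" in config.stages:
            if "crispr-dep" in config.stages:
                crispr_counts = read_count_table(paths["crispr_counts"], paths["guide_map"])
                pan_essential = _read_gene_set(paths["pan_essential"])
            if "orf-rescue" in config.stages:
                orf_counts = read_count_table(paths["orf_counts"], paths["orf_map"])
        if "expression" in paths:
            expression = pd.read_csv(paths["expression"], sep="\t", index_col=0)
        if "expression_labels" in paths:
            lab = pd.read_csv(paths["expression_labels"], sep="\t", index_col=0)
            label_groups = lab.iloc[:, 0]
        if "barcodes" in config.stages:
            barcode_counts = read_count_table(paths["barcode_counts"])
        if "synergy" in config.stages:
            dose_matrix = pd.read_csv(paths["dose_matrix"], index_col=0)
            dose_matrix.columns = dose_matrix.columns.astype(float)
        if "chip-score" in config.stages:
            chip_genes = read_intervals(paths["genes_bed"])
            if str(paths["reads_bed"]).endswith((".bedgraph", ".bg")):
                chip_reads = None
                results["_coverage"] = read_bedgraph(paths["reads_bed"])
            else:
                chip_reads = read_intervals(paths["reads_bed"])

    # ----- CRISPR dependency ----------------------------------------------
    if "crispr-dep" in config.stages:
        etp = [s for s in crispr_counts.sample_ids if s.upper().startswith("ETP")]
        final = [s for s in crispr_counts.sample_ids if s not in etp]
        unexpressed = set(
            expression.index[expression.mean(axis=1) < config.dependency.unexpressed_cutoff]
        ) if expression is not None else set()
        calls, model = score_screen(
            crispr_counts, final, etp, pan_essential, unexpressed, config.dependency
        )
        results["dependency_calls"] = calls
        results["dependency_model"] = model
        calls.to_csv(outdir / "dependency_calls.tsv", sep="\t", index=False)
        calls[["gene", "score"]].to_csv(outdir / "gene_scores.tsv", sep="\t", index=False)
        pd.DataFrame({"score": model.grid, "probability": model.prob_curve}).to_csv(
            outdir / "model_curve.tsv", sep="\t", index=False
        )

    # ----- ORF rescue -------------------------------------------------------
    if "orf-rescue" in config.stages:
        etp = [s for s in orf_counts.sample_ids if s.upper().startswith("ETP")]
        arms: dict[str, list[str]] = {}
        for s in orf_counts.sample_ids:
            if s in etp:
                continue
            arms.setdefault(s.rsplit("_", 1)[0], []).append(s)
        drug_arms = [a for a in arms if a.upper() not in {"DMSO", "VEHICLE"}]
        orf_to_gene = {f: m[0] for f, m in orf_counts.feature_meta.items()}
        arm_tables, arm_calls = {}, {}
        for arm in arms:
            table = compute_orf_lfc(orf_counts, etp, arms[arm], arm=arm,
                                    pseudocount=config.rescue.pseudocount)
            arm_tables[arm] = table
            if arm in drug_arms:
                qtab = orf_q_values(table.mean_lfc, config.rescue.min_features)
                arm_calls[arm] = call_rescue(table, qtab["q"], config.rescue, orf_to_gene)
        rescue_orfs = set().union(*(set(c.index[c["rescue"]]) for c in arm_calls.values()))
        q_only_orfs = set().union(*(set(c.index[c["q_only"]]) for c in arm_calls.values()))
        rescue_genes = {orf_to_gene[o] for o in rescue_orfs}
        q_only_genes = {orf_to_gene[o] for o in q_only_orfs} - rescue_genes
        results["rescue_calls"] = arm_calls
        results["rescue_genes"] = rescue_genes
        results["q_only_rescue_genes"] = q_only_genes
        lfc_frame = pd.DataFrame({a: t.mean_lfc for a, t in arm_tables.items()})
        lfc_frame.rename_axis("orf").to_csv(outdir / "orf_lfc.tsv", sep="\t")
        combined = pd.concat(
            [c.assign(arm=a) for a, c in arm_calls.items()], ignore_index=True
        )
        combined.to_csv(outdir / "rescue_calls.tsv", sep="\t", index=False)
        conc = {}
        if len(drug_arms) >= 2:
            a, b = drug_arms[:2]
            res = concordance(arm_tables[a].mean_lfc, arm_tables[b].mean_lfc)
            conc = {"arms": [a, b], "r_squared": res.r_squared,
                    "p_value": res.p_value, "n_orfs": res.n}
            results["concordance"] = res
        _dump_json(conc, outdir / "concordance.json")

    # ----- differential expression ------------------------------------------
    if "de" in config.stages:
        groups = sorted(label_groups.unique())
        if len(groups) != 2:
            raise ConfigurationError("expression labels must define exactly two groups")
        # vehicle/reference group first so positive SNR = suppressed under drug
        ref = "vehicle" if "vehicle" in groups else groups[0]
        labels = (label_groups == ref).to_numpy()
        marker_cfg = replace(config.marker, seed=config.seed)
        stats_table = run_marker_selection(expression[label_groups.index], labels, marker_cfg)
        supp = suppressed_set(stats_table)
        results["marker_stats"] = stats_table
        results["suppressed_genes"] = supp
        stats_table.to_csv(outdir / "marker_stats.tsv", sep="\t", index=False)
        _write_gene_set(supp, outdir / "suppressed_genes.txt")

    # ----- integration -------------------------------------------------------
    if "integrate" in config.stages:
        essential = set(
            results["dependency_calls"].index[results["dependency_calls"]["essential"]]
        )
        suppressed = results["suppressed_genes"]
        rescue_genes = results["rescue_genes"]
        universe = set(results["dependency_calls"].index) | suppressed | rescue_genes
        evidence, mediators = classify_genes(
            suppressed, essential, rescue_genes, universe,
            q_only_rescue=results.get("q_only_rescue_genes", set()),
        )
        results["evidence"] = evidence
        results["mediators"] = mediators
        evidence.to_csv(outdir / "gene_evidence.tsv", sep="\t", index=False)
        _write_gene_set(mediators.mediators, outdir / "mediators.txt")
        n = len(universe)
        tests = {}
        se = overlap_chisq(len(suppressed), len(essential),
                           len(mediators.suppressed_and_essential), n)
        tests["suppressed_vs_essential_chisq"] = dataclasses.asdict(se)
        sr = overlap_fisher(len(mediators.suppressed_and_essential), len(rescue_genes),
                            len(mediators.mediators), n)
        tests["suppressed_essential_vs_rescue_fisher"] = dataclasses.asdict(sr)
        results["overlap_tests"] = tests
        _dump_json(tests, outdir / "overlap_tests.json")

    # ----- ChIP binding scores ----------------------------------------------
    if "chip-score" in config.stages:
        coverage = results.get("_coverage")
        if coverage is None:
            coverage = chipmod.reads_to_coverage(chip_reads, config=config.chip)
        raw = chipmod.gene_binding_score(coverage, chip_genes, config.chip)
        z = chipmod.z_transform(raw.to_frame("sample_1"))
        scores = pd.DataFrame({"gene": raw.index, "raw_rpm": raw.to_numpy(),
                               "z": z.iloc[:, 0].to_numpy()})
        scores.to_csv(outdir / "binding_scores.tsv", sep="\t", index=False)
        results["binding_scores"] = scores
        target = results.get("rescue_genes", set()) & set(raw.index)
        background = set(raw.index) - target
        if len(target) >= 2 and len(background) >= 2:
            comparison = chipmod.compare_gene_sets(z, target, background)
            results["chip_comparison"] = comparison
            _dump_json(
                {"target": sorted(target), "tests": comparison.reset_index().to_dict("records")},
                outdir / "set_comparison.json",
            )
        else:
            _dump_json({"note": "target set too small for comparison"},
                       outdir / "set_comparison.json")

    # ----- barcode clonality --------------------------------------------------
    if "barcodes" in config.stages:
        etp_sample = next(s for s in barcode_counts.sample_ids if s.upper().startswith("ETP"))
        treated = [s for s in barcode_counts.sample_ids if s.startswith("JQ1")]
        vehicle = [s for s in barcode_counts.sample_ids if s.startswith("DMSO")]
        eligible = bc.filter_etp(barcode_counts, etp_sample, config.barcode)
        summary = bc.sharing_profile(barcode_counts, eligible, treated, vehicle, config.barcode)
        results["sharing_summary"] = summary
        _dump_json(dataclasses.asdict(summary), outdir / "sharing_summary.json")
        flags = pd.DataFrame({
            "barcode": barcode_counts.feature_ids,
            "eligible": [f in eligible for f in barcode_counts.feature_ids],
        })
        flags.to_csv(outdir / "barcode_flags.tsv", sep="\t", index=False)

    # ----- Bliss synergy -------------------------------------------------------
    if "synergy" in config.stages:
        res = bliss_excess(DoseMatrix(dose_matrix), config.bliss_min_excess)
        results["bliss"] = res
        res.excess.rename_axis("dose_a").to_csv(outdir / "bliss.tsv", sep="\t")
        _dump_json(
            {"mean_excess": res.mean_excess, "synergy": bool(res.synergy),
             "tolerance": res.tolerance},
            outdir / "bliss_summary.json",
        )

    # ----- provenance ----------------------------------------------------------
    provenance = {
        "seed": config.seed,
        "stages": list(config.stages),
        "dependency": dataclasses.asdict(config.dependency),
        "rescue": dataclasses.asdict(config.rescue),
        "marker": dataclasses.asdict(replace(config.marker, seed=config.seed)),
        "barcode": dataclasses.asdict(config.barcode),
        "chip": dataclasses.asdict(config.chip),
        "bliss_min_excess": config.bliss_min_excess,
        "study": dataclasses.asdict(replace(config.study, seed=config.seed))
        if "simulate" in config.stages else None,
    }
    _dump_json(provenance, outdir / "provenance.json")
    results["provenance"] = provenance
    return results


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML mapping (flat keys per stage section)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key in ("out_dir", "seed", "stages", "inputs", "bliss_min_excess"):
        if key in raw:
            kwargs[key] = tuple(raw[key]) if key == "stages" else raw[key]
    section_types = {
        "study": StudyConfig,
        "dependency": DependencyConfig,
        "rescue": RescueConfig,
        "marker": MarkerConfig,
        "barcode": bc.BarcodeConfig,
        "chip": chipmod.ChipConfig,
    }
    for name, cls in section_types.items():
        if name in raw:
            kwargs[name] = cls(**raw[name])
    return RunConfig(**kwargs)
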
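#!/usr/bin/env python
"""Intersect the three evidence layers into mediator-gene nominations.

Loads the stage outputs written by scripts 02-04, builds the per-gene
evidence table (suppressed / essential / rescue), nominates mediators as the
triple intersection, and quantifies the pairwise overlaps with chi-square and
Fisher exact tests.
"""

import argparse
import dataclasses
import json
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import pandas as pd

from betimed.integrate import classify_genes, overlap_chisq, overlap_fisher


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=Path("results/study"))
    args = parser.parse_args()

    calls = pd.read_csv(args.study / "dependency_calls.tsv", sep="\t", index_col="gene")
    essential = set(calls.index[calls["essential"]])
    suppressed = set((args.study / "suppressed_genes.txt").read_text().split())
    rescue_calls = pd.read_csv(args.study / "rescue_calls.tsv", sep="\t")
    rescue = set(rescue_calls.loc[rescue_calls["rescue"], "gene"])
    q_only = set(rescue_calls.loc[rescue_calls["q_only"], "gene"]) - rescue
    universe = set(calls.index) | suppressed | rescue

    evidence, mediators = classify_genes(suppressed, essential, rescue, universe,
                                         q_only_rescue=q_only)
    evidence.to_csv(args.study / "gene_evidence.tsv", sep="\t", index=False)
    (args.study / "mediators.txt").write_text(
        "".join(f"{g}\n" for g in sorted(mediators.mediators))
    )
    n = len(universe)
    tests = {
        "suppressed_vs_essential_chisq": dataclasses.asdict(
            overlap_chisq(len(suppressed), len(essential),
                          len(mediators.suppressed_and_essential), n)
        ),
        "suppressed_essential_vs_rescue_fisher": dataclasses.asdict(
            overlap_fisher(len(mediators.suppressed_and_essential), len(rescue),
                           len(mediators.mediators), n)
        ),
    }
    (args.study / "overlap_tests.json").write_text(json.dumps(tests, indent=2) + "\n")

    truth = set((args.study / "truth" / "truth_mediators.tsv").read_text().split())
    print(f"evidence layers: {len(suppressed)} suppressed, {len(essential)} essential, "
          f"{len(rescue)} rescue (universe {n})")
    print(f"suppressed & essential: {len(mediators.suppressed_and_essential)} genes, "
          f"chi-square p = {tests['suppressed_vs_essential_chisq']['p_value']:.3g}")
    print(f"mediators (triple intersection): {sorted(mediators.mediators)}")
    print("matches planted truth" if mediators.mediators == truth
          else f"DIFFERS from planted truth {sorted(truth)}")


if __name__ == "__main__":
    main()
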
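#!/usr/bin/env python
"""Simulate the two-cohort study the screen is designed for.

Generates two independent negative-binomial count cohorts (10 term + 20 sPTB
and 16 + 16) sharing one planted truth — five clock genes and five lincRNAs
down in sPTB, tied by a latent factor — plus a gene-set collection with five
sets seeded from the factor-carrying genes. Writes counts, sample metadata,
ground truth and GMT under results/study/.
"""

import json
from pathlib import Path

import circlinc as cl
from circlinc import io

SEED = 20230111
OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = cl.simulate_study(seed=SEED)
    for nm, cm in study.cohorts.items():
        io.write_counts(cm, OUT / f"{nm}_counts.tsv", OUT / f"{nm}_samples.tsv")
        print(f"{nm}: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} samples "
              f"({(cm.group == 'sPTB').sum()} sPTB / {(cm.group == 'term').sum()} term)")
    io.write_truth(study.truth, OUT / "truth.json")
    io.write_gmt(study.gene_sets, OUT / "gene_sets.gmt")
    meta = {
        "seed": SEED,
        "planted_lincRNAs": sorted(study.truth.planted_circadian_lincRNAs),
        "planted_clock_genes": dict(sorted(study.truth.clock_effect_directions.items())),
        "correlation_strength": study.truth.correlation_strength,
        "n_gene_sets": len(study.gene_sets.sets),
    }
    (OUT / "study_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    print(f"planted lincRNAs: {meta['planted_lincRNAs']}")
    print(f"wrote study to {OUT}")


if __name__ == "__main__":
    main()
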
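#!/usr/bin/env python
"""Simulate the study system: consensus gene, paralog pool, allelic series.

Generates a 4442 bp two-exon reference gene (4242 bp CDS, 200 bp intron),
three cluster paralogs in the 83–88% identity band, and an 8-allele series
derived from the reference by sparse SNPs, donor-copied conversion tracts,
in-frame 3 bp indels and an occasional structure-disrupting deletion.

Writes results/series/sequences.fasta plus the ground-truth JSON that the
later analysis steps are checked against.
"""

from __future__ import annotations

import json
from pathlib import Path

import allelemine as am

OUT = Path("results/series")
SEED = 20100517


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = am.SimulationConfig(
        seed=SEED, n_alleles=8, n_paralogs=3, pseudogene_prob=0.125, indel3_prob=0.25
    )
    ref, paralogs, alleles, truth = am.simulate_series(cfg)
    # split the series into the two wheat ploidy groups
    for i, a in enumerate(alleles):
        a.ploidy_group = "hexaploid" if i < 4 else "tetraploid"
    am.write_fasta([ref] + alleles + paralogs, OUT / "sequences.fasta")

    payload = {
        "seed": SEED,
        "reference_length": len(ref.bases),
        "alleles": {
            aid: {
                "snps": [[s.position, s.ref, s.alt, s.effect] for s in t.snps],
                "tracts": [[tr.donor_id, tr.start, tr.end, len(tr.diagnostic_sites)]
                           for tr in t.tracts],
                "indels": [[e.kind, e.position, e.bases] for e in t.indels],
                "pseudogene": t.pseudogene,
            }
            for aid, t in truth.alleles.items()
        },
    }
    (OUT / "truth.json").write_text(json.dumps(payload, indent=2) + "\n")

    n_pseudo = sum(t.pseudogene for t in truth.alleles.values())
    n_tracts = sum(len(t.tracts) for t in truth.alleles.values())
    print(f"reference: {len(ref.bases)} bp, CDS {truth.gene_model.cds_length} bp")
    print(f"alleles: {len(alleles)} ({n_pseudo} pseudogene), "
          f"paralogs: {len(paralogs)}, conversion tracts: {n_tracts}")
    print(f"wrote {OUT}/sequences.fasta and truth.json")


if __name__ == "__main__":
    main()
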
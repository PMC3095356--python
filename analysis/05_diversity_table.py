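#!/usr/bin/env python
"""Domain-partitioned diversity table for the simulated allelic series.

Computes, per ploidy group and per region (whole CDS, CC, NBS, interspacer,
LRR): segregating sites, sites per 100 bp, nucleotide diversity π, and the
synonymous/non-synonymous change counts with their ratio — the same layout
as the campaign's published diversity table — excluding pseudogenes.
"""

from __future__ import annotations

from pathlib import Path

import allelemine as am
from allelemine.diversity import summaries_to_frame, write_diversity_tsv
from allelemine.io_alignment import add_reference_row

SERIES = Path("results/series")
OUT = Path("results")


def main() -> None:
    seqs = am.read_fasta(SERIES / "sequences.fasta")
    roles = {s.id: s.role for s in seqs}
    ploidy = {s.id: s.ploidy_group for s in seqs}
    aln = am.align_near_identical(seqs)
    profile = am.build_consensus(aln, roles=roles, include_roles=("allele", "reference"))
    aln = add_reference_row(aln, profile.consensus, "consensus")
    consensus = profile.consensus_ungapped
    model, domains = am.default_gene_model(), am.default_domain_map()

    # exclude pseudogenes from the diversity analysis
    exclude = []
    for s in seqs:
        if roles[s.id] != "allele":
            continue
        t = am.annotate_table(
            am.call_variants(aln, s.id, "consensus"), model, consensus
        )
        if am.flag_pseudogene(t, model)[0]:
            exclude.append(s.id)

    allele_ids = [s.id for s in seqs if roles[s.id] == "allele"]
    groups = {
        g: [a for a in allele_ids if ploidy[a] == g]
        for g in ("hexaploid", "tetraploid")
    }
    rows = am.summarize_table3(
        aln, model, domains, groups, "consensus", exclude=exclude
    )
    write_diversity_tsv(rows, OUT / "diversity.tsv")
    print(f"pseudogenes excluded: {exclude or 'none'}")
    print(summaries_to_frame(rows).to_string(index=False))
    print(f"wrote {OUT}/diversity.tsv")


if __name__ == "__main__":
    main()
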
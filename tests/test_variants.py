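"""Consensus-relative variant calling, coding effects and pseudogene flags."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

import allelemine as am
from allelemine.gene_model import GeneModel
from allelemine.io_alignment import add_reference_row
from allelemine.variants import (
    VariantRecord,
    apply_variants,
    call_variants,
    write_variants_tsv,
    write_variants_vcf,
)
from .conftest import random_dna, single_exon_model


def _aligned_pair(ref: str, allele: str, allele_id: str = "a") -> am.AlleleAlignment:
    seqs = [
        am.AlleleSequence("ref", ref, role="reference"),
        am.AlleleSequence(allele_id, allele),
    ]
    return am.align_near_identical(seqs)


def test_identical_allele_yields_empty_table():
    aln = _aligned_pair("ACGTACGTACGT", "ACGTACGTACGT")
    assert len(call_variants(aln, "a", "ref")) == 0


def test_three_snps_recovered_exactly():
    rng = np.random.default_rng(4)
    ref = random_dna(rng, 600)
    allele = list(ref)
    injected = {}
    for pos in (50, 300, 550):
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[allele[pos - 1]]
        allele[pos - 1] = alt
        injected[pos] = alt
    aln = _aligned_pair(ref, "".join(allele))
    table = call_variants(aln, "a", "ref")
    assert {(r.ref_pos, r.alt_bases) for r in table} == set(injected.items())
    assert all(r.kind == "SNP" for r in table)


def test_three_bp_insertion_called_and_frame_preserving(default_model, default_domains):
    rng = np.random.default_rng(9)
    cfg = am.SimulationConfig(seed=9)
    ref, model = am.simulate_reference(cfg)
    # insert 3 bp in the LRR-encoding part of exon 2
    lrr_ref = model.cds_to_ref(1800)
    allele = ref.bases[:lrr_ref] + "GGG" + ref.bases[lrr_ref:]
    aln = _aligned_pair(ref.bases, allele)
    table = am.annotate_table(
        call_variants(aln, "a", "ref"), model, ref.bases, am.default_domain_map()
    )
    recs = list(table)
    assert len(recs) == 1
    assert recs[0].kind == "insertion"
    assert recs[0].effect == "frame_preserving_indel"
    assert recs[0].domain == "LRR"
    assert len(allele) == len(ref.bases) + 3


def test_n_bases_produce_no_calls():
    ref = "ACGTACGTACGT"
    allele = "ACGTNNGTACGT"
    aln = am.AlleleAlignment([("ref", ref), ("a", allele)], ref_id="ref")
    assert len(call_variants(aln, "a", "ref")) == 0


def test_calling_is_invariant_to_row_order(small_series):
    ref, paras, alleles, truth, aln = small_series
    aid = alleles[0].id
    shuffled = am.AlleleAlignment(rows=list(reversed(aln.rows)), ref_id="reference")
    t1 = call_variants(aln, aid, "reference")
    t2 = call_variants(shuffled, aid, "reference")
    assert t1.records == t2.records


@pytest.mark.parametrize("seed", [3, 21, 77])
def test_round_trip_reconstruction(seed):
    """Applying the called variant table to the consensus rebuilds the allele."""
    cfg = am.SimulationConfig(
        seed=seed, n_alleles=5, indel3_prob=0.4, pseudogene_prob=0.2
    )
    ref, paras, alleles, truth = am.simulate_series(cfg)
    aln = am.align_near_identical([ref] + alleles + paras)
    for a in alleles:
        table = call_variants(aln, a.id, "reference")
        assert apply_variants(ref.bases, table.records) == a.bases


# ---------------------------------------------------------------------------
# Effect classification
# ---------------------------------------------------------------------------

def test_snp_effect_examples():
    # codon TTT -> TTA is Phe->Leu (nonsynonymous); CTT -> CTA is Leu (synonymous)
    model = single_exon_model(6)
    consensus = "TTTCTT"
    r1 = am.classify_effect(
        VariantRecord("a", 3, "SNP", "T", "A"), model, consensus
    )
    r2 = am.classify_effect(
        VariantRecord("a", 6, "SNP", "T", "A"), model, consensus
    )
    assert r1.effect == "nonsynonymous"
    assert r2.effect == "synonymous"
    assert r1.region == r2.region == "exonic"


def test_intron_snp_classified_intronic(default_model):
    consensus = "A" * 4442
    pos = default_model.introns[0][0] + 10
    r = am.classify_effect(
        VariantRecord("a", pos, "SNP", "A", "G"), default_model, consensus
    )
    assert r.region == "intronic"
    assert r.effect == "intronic"


def test_45bp_cds_deletion_is_frame_preserving(default_model):
    consensus = "A" * 4442
    start = default_model.cds_to_ref(1800)
    r = am.classify_effect(
        VariantRecord("a", start, "deletion", "A" * 45, ""), default_model, consensus
    )
    assert r.effect == "frame_preserving_indel"


def test_snp_effect_matches_full_cds_translation_oracle():
    """Per-record effect equals brute-force whole-protein comparison
    for single-SNP alleles."""
    cfg = am.SimulationConfig(seed=13)
    ref, model = am.simulate_reference(cfg)
    cds = am.splice_cds(ref.bases, model)
    protein = str(Seq(cds).translate())
    rng = np.random.default_rng(13)
    for _ in range(40):
        cds_pos = int(rng.integers(1, model.cds_length + 1))
        ref_pos = model.cds_to_ref(cds_pos)
        base = ref.bases[ref_pos - 1]
        alt = "ACGT"[(("ACGT".index(base)) + 1 + int(rng.integers(3))) % 4]
        if alt == base:
            continue
        rec = am.classify_effect(
            VariantRecord("a", ref_pos, "SNP", base, alt), model, ref.bases
        )
        mutant_cds = cds[: cds_pos - 1] + alt + cds[cds_pos:]
        mutant_protein = str(Seq(mutant_cds).translate())
        expected = "synonymous" if mutant_protein == protein else "nonsynonymous"
        assert rec.effect == expected


# ---------------------------------------------------------------------------
# Pseudogene flag
# ---------------------------------------------------------------------------

def test_snp_only_allele_is_not_pseudogene(default_model):
    consensus = "A" * 4442
    recs = [
        am.classify_effect(VariantRecord("a", 30, "SNP", "A", "G"), default_model, consensus)
    ]
    flag, reason = am.flag_pseudogene(recs, default_model)
    assert flag is False and reason == ""


def test_junction_spanning_deletion_flags_pseudogene(default_model):
    consensus = "A" * 4442
    junction = default_model.exons[0][1]
    rec = am.classify_effect(
        VariantRecord("a", junction - 2, "deletion", "A" * 6, ""),
        default_model, consensus,
    )
    flag, reason = am.flag_pseudogene([rec], default_model)
    assert flag is True
    assert "junction" in reason or "frame" in reason


def test_302bp_deletion_flags_pseudogene_and_full_length_does_not():
    """A 302 bp deletion over the exon1/intron junction (4442->4140 bp) is a
    pseudogene; co-simulated full-length alleles are not."""
    cfg = am.SimulationConfig(seed=41, n_alleles=6, pseudogene_prob=0.5)
    ref, paras, alleles, truth = am.simulate_series(cfg)
    assert any(truth.alleles[a.id].pseudogene for a in alleles)
    assert any(not truth.alleles[a.id].pseudogene for a in alleles)
    aln = am.align_near_identical([ref] + alleles + paras)
    for a in alleles:
        if truth.alleles[a.id].pseudogene:
            assert len(a.bases) == 4442 - 302
        table = am.annotate_table(
            call_variants(aln, a.id, "reference"), truth.gene_model, ref.bases
        )
        flag, _ = am.flag_pseudogene(table, truth.gene_model)
        assert flag == truth.alleles[a.id].pseudogene


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------

def test_variant_outputs_round_trip(tmp_path, small_series, default_domains):
    import pandas as pd

    ref, paras, alleles, truth, aln = small_series
    table = am.VariantTable([])
    for a in alleles:
        table = table.extend(
            am.annotate_table(
                call_variants(aln, a.id, "reference"),
                truth.gene_model, ref.bases, default_domains,
            )
        )
    tsv = tmp_path / "v.tsv"
    vcf = tmp_path / "v.vcf"
    write_variants_tsv(table, tsv)
    write_variants_vcf(table, ref.bases, vcf)
    df = pd.read_csv(tsv, sep="\t")
    assert len(df) == len(table)
    lines = vcf.read_text().splitlines()
    assert lines[0] == "##fileformat=VCFv4.2"
    body = [l for l in lines if not l.startswith("#")]
    assert len(body) == len(table)
    # VCF REF fields must match the consensus at their positions
    for line in body:
        _, pos, _, ref_field, *_ = line.split("\t")
        p = int(pos)
        assert ref.bases[p - 1: p - 1 + len(ref_field)] == ref_field
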
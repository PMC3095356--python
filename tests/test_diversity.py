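"""π, segregating sites, Ka/Ks counting and the printed-table conventions."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import allelemine as am
from allelemine.diversity import (
    _codon_pathway_tallies,
    floor2,
    format_ratio,
    site_normalized_ratio,
)
from allelemine.gene_model import GeneModel
from .conftest import random_dna, single_exon_model
from .oracles import pi_bruteforce, two_change_pathway_oracle


def _aln(rows: dict[str, str], ref_id: str | None = None) -> am.AlleleAlignment:
    return am.AlleleAlignment(rows=list(rows.items()), ref_id=ref_id)


def _whole(model: GeneModel) -> tuple[int, int]:
    return (1, model.cds_length)


# ---------------------------------------------------------------------------
# Polymorphic sites
# ---------------------------------------------------------------------------

def test_identical_group_has_zero_polymorphic_sites():
    model = single_exon_model(12)
    aln = _aln({"a": "ACGTACGTACGT", "b": "ACGTACGTACGT"}, "a")
    assert am.count_polymorphic_sites(aln, model, _whole(model), ["a", "b"], "a") == 0


def test_unmutated_region_counts_zero():
    """A region kept invariant by construction scores 0 segregating sites."""
    rng = np.random.default_rng(31)
    base = random_dna(rng, 300)
    rows = {"ref": base}
    for i in range(4):
        seq = list(base)
        for p in rng.integers(150, 300, size=4):  # mutate only the second half
            seq[p] = "ACGT"[rng.integers(4)]
        rows[f"s{i}"] = "".join(seq)
    model = single_exon_model(300)
    aln = _aln(rows, "ref")
    ids = [f"s{i}" for i in range(4)]
    assert am.count_polymorphic_sites(aln, model, (1, 150), ids, "ref") == 0
    assert am.count_polymorphic_sites(aln, model, (151, 300), ids, "ref") > 0


def test_injected_segregating_sites_counted_exactly():
    rng = np.random.default_rng(77)
    base = random_dna(rng, 600)
    sites = sorted(int(p) for p in rng.choice(600, size=12, replace=False))
    rows = {"ref": base, "a": base}
    b = list(base)
    for p in sites:
        b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
    rows["b"] = "".join(b)
    model = single_exon_model(600)
    aln = _aln(rows, "ref")
    assert am.count_polymorphic_sites(aln, model, _whole(model), ["a", "b"], "ref") == 12


def test_whole_cds_count_equals_sum_over_domains(small_series, default_domains):
    ref, paras, alleles, truth, aln = small_series
    model = truth.gene_model
    ids = [a.id for a in alleles]
    top = default_domains.collapsed()
    total = am.count_polymorphic_sites(aln, model, (1, 4242), ids, "reference")
    parts = sum(
        am.count_polymorphic_sites(aln, model, (a, b), ids, "reference")
        for _, a, b in top.intervals
    )
    assert total == parts


def test_empty_group_rejected(default_model):
    aln = _aln({"a": "A" * 4442}, "a")
    with pytest.raises(ValueError):
        am.count_polymorphic_sites(aln, default_model, (1, 4242), [], "a")


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def test_pi_single_pair_definition():
    # 3 differences over 300 compared sites = 0.01
    rng = np.random.default_rng(5)
    a = random_dna(rng, 300)
    b = list(a)
    for p in (10, 100, 250):
        b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
    model = single_exon_model(300)
    aln = _aln({"a": a, "b": "".join(b)}, "a")
    assert am.nucleotide_diversity(aln, model, (1, 300), ["a", "b"], "a") == pytest.approx(0.01)


def test_pi_three_sequences_hand_computed():
    # length 9 (must be a codon multiple): pairwise diffs 1, 1, 2 -> 4/(3*9)
    s1 = "AAAAAAAAA"
    s2 = "AAAAAAAAC"  # 1 diff to s1
    s3 = "CAAAAAAAA"  # 1+... s1 vs s3: 1; s2 vs s3: 2
    model = single_exon_model(9)
    aln = _aln({"s1": s1, "s2": s2, "s3": s3}, "s1")
    pi = am.nucleotide_diversity(aln, model, (1, 9), ["s1", "s2", "s3"], "s1")
    assert pi == pytest.approx((1 + 1 + 2) / (3 * 9))


def test_pi_zero_iff_no_polymorphism():
    model = single_exon_model(30)
    aln = _aln({"a": "ACG" * 10, "b": "ACG" * 10, "c": "ACG" * 10}, "a")
    ids = ["a", "b", "c"]
    assert am.nucleotide_diversity(aln, model, (1, 30), ids, "a") == 0.0
    assert am.count_polymorphic_sites(aln, model, (1, 30), ids, "a") == 0


@pytest.mark.parametrize("seed", range(5))
def test_pi_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    n_seq = int(rng.integers(3, 7))
    L = 60
    base = random_dna(rng, L)
    rows = {}
    for i in range(n_seq):
        seq = list(base)
        for p in rng.integers(0, L, size=rng.integers(0, 8)):
            seq[p] = "ACGT"[rng.integers(4)]
        rows[f"s{i}"] = "".join(seq)
    model = single_exon_model(L)
    aln = _aln(rows, "s0")
    ids = list(rows)
    pi = am.nucleotide_diversity(aln, model, (1, L), ids, "s0")
    assert pi == pytest.approx(pi_bruteforce([rows[i] for i in ids]))


def test_plugin_pi_is_duplication_invariant():
    rng = np.random.default_rng(3)
    base = random_dna(rng, 90)
    rows = {}
    for i in range(4):
        seq = list(base)
        for p in rng.integers(0, 90, size=5):
            seq[p] = "ACGT"[rng.integers(4)]
        rows[f"s{i}"] = "".join(seq)
    model = single_exon_model(90)
    ids = list(rows)
    aln1 = _aln(rows, "s0")
    dup = dict(rows, **{f"{k}_copy": v for k, v in rows.items()})
    aln2 = _aln(dup, "s0")
    p1 = am.nucleotide_diversity(aln1, model, (1, 90), ids, "s0", estimator="plugin")
    p2 = am.nucleotide_diversity(aln2, model, (1, 90), list(dup), "s0", estimator="plugin")
    assert p2 == pytest.approx(p1, abs=1e-15)


def test_pi_requires_two_members(default_model):
    aln = _aln({"a": "A" * 4442, "b": "A" * 4442}, "a")
    with pytest.raises(ValueError):
        am.nucleotide_diversity(aln, default_model, (1, 4242), ["a"], "a")


# ---------------------------------------------------------------------------
# Ka/Ks counting
# ---------------------------------------------------------------------------

def test_single_synonymous_change():
    # TTT -> TTC is Phe -> Phe
    model = single_exon_model(3)
    aln = _aln({"a": "TTT", "b": "TTT", "c": "TTC"}, "a")
    ks, ka = am.count_substitutions(aln, model, (1, 3), ["a", "b", "c"], "a")
    assert (ks, ka) == (1, 0)


def test_single_nonsynonymous_change():
    # TTT -> TTA is Phe -> Leu
    model = single_exon_model(3)
    aln = _aln({"a": "TTT", "b": "TTT", "c": "TTA"}, "a")
    ks, ka = am.count_substitutions(aln, model, (1, 3), ["a", "b", "c"], "a")
    assert (ks, ka) == (0, 1)


def test_two_change_codon_matches_path_enumeration_oracle():
    """Pathway averaging equals the 2-order enumeration on sampled codons."""
    rng = np.random.default_rng(19)
    cases = 0
    for codon in ("TTT", "ATG", "CGA", "GGC", "TAC"):
        for (o1, o2) in itertools.combinations(range(3), 2):
            for b1 in "ACGT":
                if b1 == codon[o1]:
                    continue
                for b2 in "ACGT":
                    if b2 == codon[o2]:
                        continue
                    syn, nonsyn = _codon_pathway_tallies(
                        codon, [(o1, b1), (o2, b2)]
                    )
                    esyn, enonsyn = two_change_pathway_oracle(
                        codon, (o1, b1), (o2, b2)
                    )
                    assert syn == pytest.approx(esyn)
                    assert nonsyn == pytest.approx(enonsyn)
                    cases += 1
    assert cases > 100


def test_count_substitutions_rejects_frame_broken_region():
    model = single_exon_model(9)
    aln = _aln({"a": "ACGACGACG", "b": "ACGACGACG"}, "a")
    with pytest.raises(ValueError, match="codon-aligned"):
        am.count_substitutions(aln, model, (2, 7), ["a", "b"], "a")


# ---------------------------------------------------------------------------
# Printed-table conventions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ka,ks,expected",
    [(252, 103, 2.44), (120, 32, 3.75), (221, 66, 3.34), (38, 16, 2.37),
     (47, 37, 1.27), (28, 12, 2.33), (177, 54, 3.27), (147, 43, 3.41),
     (2, 1, 2.00), (3, 1, 3.00), (22, 9, 2.44), (311, 121, 2.57),
     (50, 38, 1.31)],
)
def test_count_ratio_truncation(ka, ks, expected):
    assert am.substitution_ratio(ka, ks) == pytest.approx(expected)


def test_ratio_undefined_when_no_synonymous_changes():
    assert am.substitution_ratio(0, 0) is None
    assert am.substitution_ratio(5, 0) is None
    assert format_ratio(None) == "-"


def test_ratio_rejects_negative_counts():
    with pytest.raises(ValueError):
        am.substitution_ratio(-1, 2)


@pytest.mark.parametrize(
    "count,length,expected",
    [(3, 474, 0.63), (147, 2508, 5.86), (0, 100, 0.0), (299, 4242, 7.04),
     (37, 198, 18.68)],
)
def test_per_100bp_truncation(count, length, expected):
    assert am.per_100bp(count, length) == pytest.approx(expected)


def test_per_100bp_rejects_zero_length():
    with pytest.raises(ValueError):
        am.per_100bp(1, 0)


def test_floor2_truncates_not_rounds():
    assert floor2(2.4466) == 2.44
    assert floor2(2.375) == 2.37
    assert floor2(3.75) == 3.75


# ---------------------------------------------------------------------------
# Site-normalized alternative
# ---------------------------------------------------------------------------

def test_site_normalized_ratio_is_labelled_and_consistent():
    res = site_normalized_ratio("TTT" * 100, ks_count=3, ka_count=6)
    assert res["method"] == "nei_gojobori_pn_ps_jc"
    assert res["syn_sites"] + res["nonsyn_sites"] == pytest.approx(300)
    assert res["pS"] == pytest.approx(3 / res["syn_sites"])
    assert res["dN_dS"] is not None


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

def test_summary_table_shape_and_groups(small_series, default_domains):
    ref, paras, alleles, truth, aln = small_series
    ids = [a.id for a in alleles]
    groups = {"hexaploid": ids[:3], "tetraploid": ids[3:]}
    rows = am.summarize_table3(
        aln, truth.gene_model, default_domains, groups, "reference"
    )
    assert len(rows) == 15  # 3 groups x 5 regions
    assert {r.group for r in rows} == {"hexaploid", "tetraploid", "combined"}
    by_key = {(r.group, r.region): r for r in rows}
    assert by_key[("combined", "CDS")].aligned_sites == 4242
    # combined polymorphic count >= each group's count (set union property)
    for region in ("CDS", "CC", "NBS", "interspacer", "LRR"):
        combined = by_key[("combined", region)].polymorphic_sites
        assert combined >= by_key[("hexaploid", region)].polymorphic_sites
        assert combined >= by_key[("tetraploid", region)].polymorphic_sites


def test_summary_single_group_has_five_rows(small_series, default_domains):
    ref, paras, alleles, truth, aln = small_series
    rows = am.summarize_table3(
        aln, truth.gene_model, default_domains,
        {"all": [a.id for a in alleles]}, "reference",
    )
    assert len(rows) == 5
    assert [r.region for r in rows] == ["CDS", "CC", "NBS", "interspacer", "LRR"]


def test_summary_cells_match_ground_truth():
    """On a SNP-only panel every polymorphic-site cell equals the count of
    distinct injected positions in that region, and π matches brute force."""
    cfg = am.SimulationConfig(
        seed=29, n_alleles=6, snp_mean=8.0, n_conversion_mean=0.0,
        indel3_prob=0.0, pseudogene_prob=0.0, n_paralogs=0,
    )
    ref, _, alleles, truth = am.simulate_series(cfg)
    aln = am.align_near_identical(
        [am.AlleleSequence("reference", ref.bases, role="reference")]
        + [am.AlleleSequence(a.id, a.bases) for a in alleles]
    )
    model = truth.gene_model
    domains = am.default_domain_map()
    ids = [a.id for a in alleles]
    rows = am.summarize_table3(aln, model, domains, {"all": ids}, "reference")
    by_region = {r.region: r for r in rows}

    # expected segregating sites per region from the recorded truth
    def seg_sites(lo, hi):
        sites = set()
        for a in alleles:
            for s in truth.alleles[a.id].snps:
                cds = model.ref_to_cds(s.position)
                if cds is not None and lo <= cds <= hi:
                    sites.add(s.position)
        return len(sites)

    assert by_region["CDS"].polymorphic_sites == seg_sites(1, 4242)
    for name, a, b in domains.collapsed().intervals:
        assert by_region[name].polymorphic_sites == seg_sites(a, b)

    cds_rows = [
        "".join(a.bases[x - 1] for x in
                (model.cds_to_ref(p) for p in range(1, 4243)))
        for a in alleles
    ]
    assert by_region["CDS"].pi == pytest.approx(pi_bruteforce(cds_rows))


def test_summary_tsv_output(tmp_path, small_series, default_domains):
    import pandas as pd

    ref, paras, alleles, truth, aln = small_series
    rows = am.summarize_table3(
        aln, truth.gene_model, default_domains,
        {"all": [a.id for a in alleles]}, "reference",
    )
    p = tmp_path / "div.tsv"
    from allelemine.diversity import write_diversity_tsv

    write_diversity_tsv(rows, p)
    df = pd.read_csv(p, sep="\t")
    assert list(df.columns)[:5] == [
        "group", "region", "aligned_sites", "gapped_sites", "polymorphic_sites"
    ]
    assert len(df) == 5
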
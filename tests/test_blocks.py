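"""Block segmentation, donor matching, chimera reports, ploidy profiles."""

from __future__ import annotations

import numpy as np
import pytest

import allelemine as am
from allelemine.blocks import window_shared_sites
from allelemine.variants import VariantRecord, VariantTable, call_variants
from .conftest import random_dna


def _table(positions, allele_id="a", alt="G", ref="A"):
    return VariantTable(
        [VariantRecord(allele_id, p, "SNP", ref, alt) for p in positions]
    )


def test_two_distant_snps_form_no_block():
    blocks, isolated = am.segment_blocks(_table([1000, 2000]), "a")
    assert blocks == []
    assert len(isolated) == 2


def test_hand_evaluated_clustering():
    # {100,150,220} cluster (gaps 50,70 <= 250); 3000 is isolated
    blocks, isolated = am.segment_blocks(_table([100, 150, 220, 3000]), "a")
    assert len(blocks) == 1
    assert (blocks[0].start, blocks[0].end) == (100, 220)
    assert blocks[0].member_positions == [100, 150, 220]
    assert [r.ref_pos for r in isolated] == [3000]


def test_segmentation_is_a_partition():
    rng = np.random.default_rng(8)
    positions = sorted(rng.choice(np.arange(1, 4000), size=40, replace=False))
    table = _table([int(p) for p in positions])
    blocks, isolated = am.segment_blocks(table, "a")
    seen = [p for b in blocks for p in b.member_positions] + [
        r.ref_pos for r in isolated
    ]
    assert sorted(seen) == list(positions)
    for b in blocks:
        assert b.site_count >= 3
        gaps = np.diff(b.member_positions)
        assert (gaps <= 250).all()


def _tract_fixture(seed=17, n_diag=11):
    """Reference + donor paralog + one allele carrying a donor tract."""
    rng = np.random.default_rng(seed)
    ref = random_dna(rng, 2000)
    donor = list(ref)
    # donor differs at n_diag sites clustered within a 400 bp window
    diag_pos = sorted(rng.choice(np.arange(800, 1200), size=n_diag, replace=False))
    for p in diag_pos:
        donor[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[donor[p]]
    donor = "".join(donor)
    allele = ref[:790] + donor[790:1250] + ref[1250:]
    seqs = [
        am.AlleleSequence("ref", ref, role="reference"),
        am.AlleleSequence("allele", allele),
        am.AlleleSequence("donor", donor, role="paralog"),
    ]
    aln = am.align_near_identical(seqs)
    return aln, [int(p) + 1 for p in diag_pos]


def test_simulated_tract_forms_single_block_with_all_sites():
    aln, diag = _tract_fixture(n_diag=11)
    table = call_variants(aln, "allele", "ref")
    blocks, isolated = am.segment_blocks(table, "allele")
    assert len(blocks) == 1
    assert blocks[0].member_positions == diag
    assert isolated == []


def test_block_match_identical_partial_unique():
    aln, diag = _tract_fixture(n_diag=9)
    table = call_variants(aln, "allele", "ref")
    blocks, _ = am.segment_blocks(table, "allele")
    matches = am.match_block(blocks[0], aln, ["donor", "ref"], "ref")
    by_id = {m.donor_id: m for m in matches}
    assert by_id["donor"].shared_sites == by_id["donor"].total_sites == 9
    assert by_id["donor"].classification == "identical"
    # the reference equals the consensus everywhere: zero sharing
    assert by_id["ref"].shared_sites == 0
    assert by_id["ref"].classification == "unique"
    assert matches[0].donor_id == "donor"


def test_partial_sharing_after_private_overwrites():
    """A donor tract later overwritten by 2 private SNPs scores 7/9 partial."""
    rng = np.random.default_rng(23)
    ref = random_dna(rng, 2000)
    donor = list(ref)
    diag = sorted(rng.choice(np.arange(900, 1150), size=9, replace=False))
    for p in diag:
        donor[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[donor[p]]
    donor = "".join(donor)
    allele = list(ref[:880] + donor[880:1200] + ref[1200:])
    for p in diag[:2]:  # private SNPs distinct from both donor and reference
        current = allele[p]
        allele[p] = next(b for b in "ACGT" if b not in (current, ref[p]))
    aln = am.align_near_identical(
        [
            am.AlleleSequence("ref", ref, role="reference"),
            am.AlleleSequence("allele", "".join(allele)),
            am.AlleleSequence("donor", donor, role="paralog"),
        ]
    )
    table = call_variants(aln, "allele", "ref")
    blocks, _ = am.segment_blocks(table, "allele")
    assert len(blocks) == 1
    m = am.match_block(blocks[0], aln, ["donor"], "ref")[0]
    assert (m.shared_sites, m.total_sites) == (7, 9)
    assert m.classification == "partial"


def test_self_match_is_always_total(small_series):
    ref, paras, alleles, truth, aln = small_series
    for a in alleles:
        table = call_variants(aln, a.id, "reference")
        blocks, _ = am.segment_blocks(table, a.id)
        for b in blocks:
            m = am.match_block(b, aln, [a.id], "reference")[0]
            assert m.shared_sites == m.total_sites
            assert m.classification == "identical"


def test_match_output_invariant_to_donor_order():
    aln, _ = _tract_fixture()
    table = call_variants(aln, "allele", "ref")
    blocks, _ = am.segment_blocks(table, "allele")
    m1 = am.match_block(blocks[0], aln, ["donor", "ref"], "ref")
    m2 = am.match_block(blocks[0], aln, ["ref", "donor"], "ref")
    assert [(m.donor_id, m.shared_sites) for m in m1] == [
        (m.donor_id, m.shared_sites) for m in m2
    ]


def test_missing_donor_rejected():
    aln, _ = _tract_fixture()
    table = call_variants(aln, "allele", "ref")
    blocks, _ = am.segment_blocks(table, "allele")
    with pytest.raises(KeyError):
        am.match_block(blocks[0], aln, ["nope"], "ref")


def test_window_query_counts_shared_sites():
    aln, diag = _tract_fixture(n_diag=9)
    shared, total = window_shared_sites(aln, "allele", "donor", (1, 2000), "ref")
    assert (shared, total) == (9, 9)
    lo = min(diag)
    shared2, total2 = window_shared_sites(aln, "allele", "donor", (lo, lo), "ref")
    assert (shared2, total2) == (1, 1)


# ---------------------------------------------------------------------------
# Chimera reports
# ---------------------------------------------------------------------------

def test_snp_only_allele_report():
    report = am.chimera_report("x", [], [], {}, isolated=[])
    assert report["summary"] == "SNP-only allele"
    assert report["n_blocks"] == 0


def test_paralog_donor_flagged_in_report():
    aln, _ = _tract_fixture()
    table = call_variants(aln, "allele", "ref")
    blocks, isolated = am.segment_blocks(table, "allele")
    matches = [am.match_block(b, aln, ["donor", "ref"], "ref") for b in blocks]
    rep = am.chimera_report(
        "allele", blocks, matches, {"donor": "paralog", "ref": "reference"}, isolated
    )
    assert rep["blocks"][0]["paralog_derived"] is True
    assert rep["blocks"][0]["best_donors"][0]["donor_id"] == "donor"


def test_tied_donors_listed_in_deterministic_order():
    aln, _ = _tract_fixture()
    # add an exact copy of the donor under another name: a guaranteed tie
    rows = list(aln.rows) + [("donor2", aln.row("donor"))]
    aln2 = am.AlleleAlignment(rows=rows, ref_id="ref")
    table = call_variants(aln2, "allele", "ref")
    blocks, isolated = am.segment_blocks(table, "allele")
    matches = [am.match_block(b, aln2, ["donor2", "donor"], "ref") for b in blocks]
    rep = am.chimera_report("allele", blocks, matches, {}, isolated)
    best = rep["blocks"][0]["best_donors"]
    assert [d["donor_id"] for d in best] == ["donor", "donor2"]


# ---------------------------------------------------------------------------
# Ploidy-group profile
# ---------------------------------------------------------------------------

def _blocks_for(variant_positions, allele_id, alt="G"):
    table = _table(variant_positions, allele_id, alt=alt)
    blocks, _ = am.segment_blocks(table, allele_id)
    return blocks


def test_group_specific_footprint_detected():
    """A tract footprint given only to group-B members is reported B-specific."""
    positions = [500, 600, 700, 800]
    blocks_by_allele = {}
    labels = {}
    for i in range(16):
        aid = f"tet_{i}"
        blocks_by_allele[aid] = _blocks_for(positions, aid)
        labels[aid] = "tetraploid"
    for i in range(7):
        aid = f"hex_{i}"
        blocks_by_allele[aid] = []
        labels[aid] = "hexaploid"
    profile = am.ploidy_block_profile(blocks_by_allele, labels)
    assert len(profile) == 1
    assert profile[0]["status"] == "specific:tetraploid"
    assert profile[0]["n_carriers"] == 16


def test_footprint_shared_across_groups_reported_shared():
    positions = [500, 600, 700, 800]
    blocks_by_allele = {
        f"tet_{i}": _blocks_for(positions, f"tet_{i}") for i in range(5)
    }
    labels = {f"tet_{i}": "tetraploid" for i in range(5)}
    # one hexaploid allele partially carries the footprint (3 of 4 sites)
    blocks_by_allele["hex_0"] = _blocks_for(positions[:3], "hex_0")
    labels["hex_0"] = "hexaploid"
    profile = am.ploidy_block_profile(blocks_by_allele, labels)
    assert profile[0]["status"] == "shared"
    assert "hex_0" in profile[0]["carriers_by_group"]["hexaploid"]


def test_all_consensus_panel_gives_empty_profile():
    profile = am.ploidy_block_profile({"a": [], "b": []}, {"a": "hexaploid", "b": "tetraploid"})
    assert profile == []
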
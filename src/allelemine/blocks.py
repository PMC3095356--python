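"""Polymorphic-block segmentation, donor matching and chimera reports.

Alleles of a resistance-gene series tend to differ from the consensus either
by scattered SNPs or by dense clusters of polymorphisms ("blocks") that are
footprints of gene conversion or recombination with another allele or a
paralog.  This module clusters an allele's variant positions into blocks,
scores each block against a donor panel (sharing = identical non-consensus
base at the homologous alignment column), and assembles per-allele chimera
reports plus a ploidy-group block profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .io_alignment import GAP, AlleleAlignment, column_maps
from .variants import VariantRecord, VariantTable

DEFAULT_MIN_SITES = 3
DEFAULT_MAX_GAP = 250
DEFAULT_PARTIAL_THRESHOLD = 0.40


@dataclass
class PolymorphicBlock:
    """A cluster of nearby polymorphic sites of one allele (consensus coords)."""

    allele_id: str
    start: int
    end: int
    member_positions: list[int]
    member_records: list[VariantRecord] = field(default_factory=list)

    @property
    def site_count(self) -> int:
        return len(self.member_positions)


@dataclass
class BlockMatch:
    """Sharing evidence between a block and one donor sequence."""

    block: PolymorphicBlock
    donor_id: str
    shared_sites: int
    total_sites: int
    classification: str  # identical | partial | unique

    @property
    def fraction(self) -> float:
        return self.shared_sites / self.total_sites if self.total_sites else 0.0


def segment_blocks(
    variant_table: VariantTable,
    allele_id: str,
    min_sites: int = DEFAULT_MIN_SITES,
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[list[PolymorphicBlock], list[VariantRecord]]:
    """Greedy left-to-right clustering of an allele's polymorphic sites.

    A site joins the current cluster when it lies within ``max_gap`` bp of the
    previous site; clusters with at least ``min_sites`` members become blocks
    and the remaining sites are returned as isolated SNPs/indels.  Every
    polymorphic site ends up in exactly one block or in the isolated list.
    """
    recs = sorted(variant_table.for_allele(allele_id), key=lambda r: (r.ref_pos, r.kind))
    blocks: list[PolymorphicBlock] = []
    isolated: list[VariantRecord] = []
    cluster: list[VariantRecord] = []

    def close_cluster() -> None:
        nonlocal cluster
        if len(cluster) >= min_sites:
            positions = [r.ref_pos for r in cluster]
            blocks.append(
                PolymorphicBlock(
                    allele_id=allele_id,
                    start=positions[0],
                    end=max(r.end for r in cluster),
                    member_positions=positions,
                    member_records=list(cluster),
                )
            )
        else:
            isolated.extend(cluster)
        cluster = []

    for r in recs:
        if cluster and r.ref_pos - cluster[-1].ref_pos > max_gap:
            close_cluster()
        cluster.append(r)
    close_cluster()
    return blocks, isolated


def match_block(
    block: PolymorphicBlock,
    alignment: AlleleAlignment,
    donor_ids: Sequence[str],
    ref_id: str | None = None,
    partial_threshold: float = DEFAULT_PARTIAL_THRESHOLD,
) -> list[BlockMatch]:
    """Score a block against each donor, sorted by shared sites (desc, id asc).

    A member site counts as shared when the donor carries the identical
    non-consensus base at the homologous alignment column.  Only
    substitution-type members are comparable; member sites where the donor has
    a gap or N are excluded from that donor's shared/total counts.
    """
    ref_id = ref_id or alignment.ref_id
    _, refpos_to_col = column_maps(alignment, ref_id)
    allele_row = alignment.row(block.allele_id)
    snp_members = [r for r in block.member_records if r.kind == "SNP"]

    matches: list[BlockMatch] = []
    for donor_id in donor_ids:
        if donor_id not in alignment:
            raise KeyError(f"donor {donor_id!r} not in alignment")
        donor_row = alignment.row(donor_id)
        shared = total = 0
        for r in snp_members:
            col = refpos_to_col[r.ref_pos]
            d = donor_row[col]
            if d in (GAP, "N"):
                continue
            total += 1
            if d == allele_row[col]:
                shared += 1
        if total and shared == total:
            cls = "identical"
        elif total and shared / total >= partial_threshold:
            cls = "partial"
        else:
            cls = "unique"
        matches.append(BlockMatch(block, donor_id, shared, total, cls))
    matches.sort(key=lambda m: (-m.shared_sites, m.donor_id))
    return matches


def window_shared_sites(
    alignment: AlleleAlignment,
    allele_id: str,
    donor_id: str,
    window: tuple[int, int],
    ref_id: str | None = None,
) -> tuple[int, int]:
    """(shared, total) polymorphic sites of an allele within a reference window.

    Window-query view: all consensus-relative substitution sites of the allele
    inside [start, end] are counted, regardless of block segmentation.
    """
    ref_id = ref_id or alignment.ref_id
    ref_row = alignment.row(ref_id)
    allele_row = alignment.row(allele_id)
    donor_row = alignment.row(donor_id)
    col_to_refpos, _ = column_maps(alignment, ref_id)
    shared = total = 0
    for col in range(alignment.length):
        pos, is_ins = col_to_refpos[col]
        if is_ins or not (window[0] <= pos <= window[1]):
            continue
        rc, ac, dc = ref_row[col], allele_row[col], donor_row[col]
        if ac in (GAP, "N") or rc == GAP or ac == rc:
            continue
        if dc in (GAP, "N"):
            continue
        total += 1
        if dc == ac:
            shared += 1
    return shared, total


def chimera_report(
    allele_id: str,
    blocks: Sequence[PolymorphicBlock],
    matches_per_block: Sequence[Sequence[BlockMatch]],
    roles: Mapping[str, str] | None = None,
    isolated: Sequence[VariantRecord] = (),
) -> dict:
    """Per-allele report: consensus backbone plus best donor per block.

    Donors tied on shared sites are all listed (deterministic id order);
    blocks whose best donor is a paralog are flagged as paralog-derived.
    """
    roles = roles or {}
    entries = []
    for block, matches in zip(blocks, matches_per_block):
        if matches:
            best_count = matches[0].shared_sites
            best = [m for m in matches if m.shared_sites == best_count]
        else:
            best = []
        entries.append(
            {
                "start": block.start,
                "end": block.end,
                "n_sites": block.site_count,
                "best_donors": [
                    {
                        "donor_id": m.donor_id,
                        "shared": m.shared_sites,
                        "total": m.total_sites,
                        "classification": m.classification,
                        "donor_role": roles.get(m.donor_id, "allele"),
                    }
                    for m in best
                ],
                "paralog_derived": bool(
                    best and roles.get(best[0].donor_id, "allele") == "paralog"
                ),
            }
        )
    return {
        "allele_id": allele_id,
        "backbone": "consensus",
        "n_blocks": len(blocks),
        "n_isolated_snps": len(list(isolated)),
        "blocks": entries,
        "summary": "SNP-only allele" if not blocks else f"{len(blocks)} block(s)",
    }


# ---------------------------------------------------------------------------
# Ploidy-group block profile
# ---------------------------------------------------------------------------

def _footprint(block: PolymorphicBlock) -> tuple[tuple[int, str], ...]:
    return tuple(
        sorted((r.ref_pos, r.alt_bases) for r in block.member_records if r.kind == "SNP")
    )


def ploidy_block_profile(
    blocks_by_allele: Mapping[str, Sequence[PolymorphicBlock]],
    group_labels: Mapping[str, str],
    min_group_members: int = 2,
    overlap_frac: float = 0.5,
) -> list[dict]:
    """Summarise which block footprints are private to or shared across groups.

    A footprint is a set of (position, alt base) sites.  Exact footprints are
    pooled by multiplicity; a block carries a canonical footprint when it
    shares at least ``overlap_frac`` of that footprint's sites, so partially
    overwritten copies of the same conversion tract still register as
    carriers.  A footprint with at least ``min_group_members`` carriers in
    exactly one group (and none elsewhere) is flagged group-specific.
    """
    all_blocks = [
        (aid, b) for aid, blist in sorted(blocks_by_allele.items()) for b in blist
    ]
    exact: dict[tuple, int] = {}
    for _, b in all_blocks:
        fp = _footprint(b)
        if fp:
            exact[fp] = exact.get(fp, 0) + 1
    canonical = sorted(exact, key=lambda fp: (-exact[fp], fp))

    assigned: dict[tuple, list[tuple[str, PolymorphicBlock]]] = {fp: [] for fp in canonical}
    for aid, b in all_blocks:
        fp = _footprint(b)
        if not fp:
            continue
        fp_set = set(fp)
        for cand in canonical:
            overlap = len(fp_set & set(cand)) / len(cand)
            if overlap >= overlap_frac:
                assigned[cand].append((aid, b))
                break
        else:
            assigned.setdefault(fp, []).append((aid, b))
            canonical.append(fp)

    profile: list[dict] = []
    for fp in canonical:
        carriers = assigned[fp]
        if not carriers:
            continue
        by_group: dict[str, list[str]] = {}
        for aid, _ in carriers:
            by_group.setdefault(group_labels.get(aid, "unknown"), []).append(aid)
        groups_present = sorted(by_group)
        if len(groups_present) == 1 and len(by_group[groups_present[0]]) >= min_group_members:
            status = f"specific:{groups_present[0]}"
        elif len(groups_present) > 1:
            status = "shared"
        else:
            status = "singleton"
        positions = [p for p, _ in fp]
        profile.append(
            {
                "footprint_id": f"fp_{min(positions)}_{max(positions)}_{len(fp)}",
                "n_sites": len(fp),
                "span": (min(positions), max(positions)),
                "carriers_by_group": {g: sorted(a) for g, a in by_group.items()},
                "n_carriers": len(carriers),
                "status": status,
            }
        )
    profile.sort(key=lambda e: (-e["n_carriers"], e["footprint_id"]))
    return profile


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_blocks_tsv(blocks: Sequence[PolymorphicBlock], path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "allele_id": b.allele_id,
                "start": b.start,
                "end": b.end,
                "n_sites": b.site_count,
                "positions": ",".join(map(str, b.member_positions)),
            }
            for b in blocks
        ],
        columns=["allele_id", "start", "end", "n_sites", "positions"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_matches_tsv(matches: Sequence[BlockMatch], path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "allele_id": m.block.allele_id,
                "block_start": m.block.start,
                "block_end": m.block.end,
                "donor_id": m.donor_id,
                "shared_sites": m.shared_sites,
                "total_sites": m.total_sites,
                "classification": m.classification,
            }
            for m in matches
        ],
        columns=[
            "allele_id", "block_start", "block_end", "donor_id",
            "shared_sites", "total_sites", "classification",
        ],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_chimera_json(reports: Sequence[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(list(reports), indent=2) + "\n")
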
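"""Consensus-relative variant calling and coding-effect classification.

Every allele is described as a set of polymorphisms against the consensus of
the allelic series: SNPs, anchored insertions and deletions, in 1-based
consensus coordinates.  Coding effects are judged per record against the
consensus codon background; indels inside the CDS are frame-preserving iff
their length is a multiple of three, and structure-disrupting deletions
(frameshifts, or deletions removing an exon/intron junction) mark an allele
as a putative pseudogene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .gene_model import DomainMap, GeneModel, codon_at, domain_of, splice_cds
from .io_alignment import GAP, AlleleAlignment, column_maps

KINDS = ("SNP", "insertion", "deletion")
EFFECTS = (
    "synonymous",
    "nonsynonymous",
    "intronic",
    "frame_preserving_indel",
    "frame_disrupting",
    "not_applicable",
)


@dataclass(frozen=True)
class VariantRecord:
    """One polymorphism of one allele relative to the consensus.

    SNP: ref_pos is the substituted position, |ref_bases| = |alt_bases| = 1.
    deletion: ref_pos is the first deleted consensus position, alt_bases = ''.
    insertion: the inserted bases sit immediately after ref_pos (ref_bases = '').
    """

    allele_id: str
    ref_pos: int
    kind: str
    ref_bases: str
    alt_bases: str
    region: str = "unknown"
    effect: str = "unknown"
    domain: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "SNP":
            if len(self.ref_bases) != 1 or len(self.alt_bases) != 1:
                raise ValueError("SNP must have single ref and alt bases")
            if self.ref_bases == self.alt_bases:
                raise ValueError("SNP ref and alt are identical")
        elif self.kind == "insertion" and not self.alt_bases:
            raise ValueError("insertion with no inserted bases")
        elif self.kind == "deletion" and not self.ref_bases:
            raise ValueError("deletion with no deleted bases")

    @property
    def length(self) -> int:
        return len(self.alt_bases) if self.kind == "insertion" else len(self.ref_bases)

    @property
    def end(self) -> int:
        """Last reference position touched (== ref_pos for SNP/insertion anchor)."""
        if self.kind == "deletion":
            return self.ref_pos + len(self.ref_bases) - 1
        return self.ref_pos


@dataclass
class VariantTable:
    """Sorted, indexed collection of variant records."""

    records: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records, key=lambda r: (r.allele_id, r.ref_pos, r.kind, r.alt_bases)
        )
        seen = set()
        for r in self.records:
            key = (r.allele_id, r.ref_pos, r.kind, r.alt_bases)
            if key in seen:
                raise ValueError(f"duplicate variant record {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def for_allele(self, allele_id: str) -> list[VariantRecord]:
        return [r for r in self.records if r.allele_id == allele_id]

    def at_position(self, ref_pos: int) -> list[VariantRecord]:
        return [r for r in self.records if r.ref_pos == ref_pos]

    @property
    def allele_ids(self) -> list[str]:
        return sorted({r.allele_id for r in self.records})

    def extend(self, other: "VariantTable") -> "VariantTable":
        return VariantTable(self.records + other.records)


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def _left_normalize(records: list[VariantRecord], consensus: str) -> list[VariantRecord]:
    """Left-align indels against the ungapped consensus.

    A shift is only taken while the sequence content is invariant and the new
    span does not collide with another record of the same allele, so the
    record set stays unambiguous and round-trippable.
    """
    occupied = {(r.allele_id, p) for r in records if r.kind == "SNP" for p in (r.ref_pos,)}
    out: list[VariantRecord] = []
    for r in records:
        if r.kind == "deletion":
            p, s = r.ref_pos, r.ref_bases
            while p > 1 and consensus[p - 2] == s[-1] and (r.allele_id, p - 1) not in occupied:
                p -= 1
                s = consensus[p - 1] + s[:-1]
            r = replace(r, ref_pos=p, ref_bases=s)
        elif r.kind == "insertion":
            a, s = r.ref_pos, r.alt_bases
            while a >= 1 and consensus[a - 1] == s[-1] and (r.allele_id, a) not in occupied:
                s = s[-1] + s[:-1]
                a -= 1
            r = replace(r, ref_pos=a, alt_bases=s)
        out.append(r)
    return out


def call_variants(
    alignment: AlleleAlignment,
    allele_id: str,
    ref_id: str | None = None,
) -> VariantTable:
    """Call SNPs and indels of one allele row against the reference row.

    One record per mismatching column and per maximal gap run; N in the allele
    is missing data and produces no call.  Positions are 1-based ungapped
    reference (consensus) coordinates; indels are left-normalized.
    """
    ref_id = ref_id or alignment.ref_id
    if ref_id is None:
        raise ValueError("no reference row designated")
    if allele_id not in alignment:
        raise KeyError(f"allele {allele_id!r} not in alignment")
    ref_row = alignment.row(ref_id)
    allele_row = alignment.row(allele_id)
    col_to_refpos, _ = column_maps(alignment, ref_id)
    consensus = ref_row.replace(GAP, "")

    records: list[VariantRecord] = []
    del_start: int | None = None
    del_bases: list[str] = []
    ins_anchor: int | None = None
    ins_bases: list[str] = []

    def flush_del() -> None:
        nonlocal del_start, del_bases
        if del_start is not None:
            records.append(
                VariantRecord(allele_id, del_start, "deletion", "".join(del_bases), "")
            )
            del_start, del_bases = None, []

    def flush_ins() -> None:
        nonlocal ins_anchor, ins_bases
        if ins_anchor is not None:
            records.append(
                VariantRecord(allele_id, ins_anchor, "insertion", "", "".join(ins_bases))
            )
            ins_anchor, ins_bases = None, []

    for col in range(alignment.length):
        rc, ac = ref_row[col], allele_row[col]
        pos, is_ins_col = col_to_refpos[col]
        if rc == GAP and ac == GAP:
            continue  # nothing in either sequence at this column
        if rc == GAP:  # allele has extra bases relative to the reference
            flush_del()
            if ac == "N":
                flush_ins()
                continue
            if ins_anchor is None:
                ins_anchor = pos
            ins_bases.append(ac)
            continue
        # reference has a base here
        flush_ins()
        if ac == GAP:
            if del_start is None:
                del_start = pos
            del_bases.append(rc)
            continue
        flush_del()
        if ac == "N":
            continue
        if ac != rc:
            records.append(VariantRecord(allele_id, pos, "SNP", rc, ac))
    flush_del()
    flush_ins()

    return VariantTable(_left_normalize(records, consensus))


def apply_variants(consensus: str, records: Sequence[VariantRecord]) -> str:
    """Reconstruct an allele sequence by applying its records to the consensus."""
    kind_rank = {"deletion": 0, "SNP": 1, "insertion": 2}
    seq = list(consensus)
    for r in sorted(records, key=lambda r: (r.ref_pos, kind_rank[r.kind]), reverse=True):
        if r.kind == "SNP":
            if seq[r.ref_pos - 1] != r.ref_bases:
                raise ValueError(
                    f"SNP ref base mismatch at {r.ref_pos}: "
                    f"{seq[r.ref_pos - 1]} != {r.ref_bases}"
                )
            seq[r.ref_pos - 1] = r.alt_bases
        elif r.kind == "deletion":
            if "".join(seq[r.ref_pos - 1: r.end]) != r.ref_bases:
                raise ValueError(f"deletion ref mismatch at {r.ref_pos}")
            del seq[r.ref_pos - 1: r.end]
        else:
            seq[r.ref_pos: r.ref_pos] = list(r.alt_bases)
    return "".join(seq)


# ---------------------------------------------------------------------------
# Effect classification
# ---------------------------------------------------------------------------

def _spans_splice_junction(record: VariantRecord, model: GeneModel) -> bool:
    """True when a deletion removes both sides of an exon/intron boundary."""
    if record.kind != "deletion":
        return False
    boundaries: list[tuple[int, int]] = []
    for a, b in model.introns:
        boundaries.append((a - 1, a))  # last exon base, first intron base
        boundaries.append((b, b + 1))  # last intron base, first exon base
    return any(record.ref_pos <= x and record.end >= y for x, y in boundaries)


def classify_effect(
    record: VariantRecord,
    model: GeneModel,
    consensus: str,
    domain_map: DomainMap | None = None,
) -> VariantRecord:
    """Return the record annotated with region, coding effect and domain.

    SNP effects substitute the alt base into the consensus codon (the other
    two positions stay at consensus state) and compare translated amino
    acids.  Indel effects use length mod 3 inside the CDS; a deletion that
    removes a splice junction is frame_disrupting regardless of length.
    """
    region = model.region_of(record.ref_pos)
    domain = ""
    effect: str
    if record.kind == "SNP":
        if region == "exonic":
            cds_pos = model.ref_to_cds(record.ref_pos)
            assert cds_pos is not None
            codon_idx, offset = codon_at(cds_pos, model.cds_length)
            cds = splice_cds(consensus, model)
            codon = cds[(codon_idx - 1) * 3: codon_idx * 3]
            mutant = codon[: offset - 1] + record.alt_bases + codon[offset:]
            aa_ref = str(Seq(codon).translate())
            aa_alt = str(Seq(mutant).translate())
            effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
            if domain_map is not None:
                domain = domain_of(cds_pos, domain_map)
        elif region == "intronic":
            effect = "intronic"
        else:
            effect = "not_applicable"
    else:
        overlaps_cds = any(
            record.ref_pos <= b and record.end >= a for a, b in model.exons
        )
        if record.kind == "deletion" and _spans_splice_junction(record, model):
            effect = "frame_disrupting"
        elif overlaps_cds:
            effect = (
                "frame_preserving_indel" if record.length % 3 == 0 else "frame_disrupting"
            )
            if domain_map is not None:
                cds_pos = model.ref_to_cds(record.ref_pos)
                if cds_pos is None and record.kind == "deletion":
                    for p in range(record.ref_pos, record.end + 1):
                        cds_pos = model.ref_to_cds(p)
                        if cds_pos is not None:
                            break
                if cds_pos is not None:
                    domain = domain_of(cds_pos, domain_map)
        elif region == "intronic":
            effect = "intronic"
        else:
            effect = "not_applicable"
    return replace(record, region=region, effect=effect, domain=domain)


def annotate_table(
    table: VariantTable,
    model: GeneModel,
    consensus: str,
    domain_map: DomainMap | None = None,
) -> VariantTable:
    return VariantTable(
        [classify_effect(r, model, consensus, domain_map) for r in table]
    )


def flag_pseudogene(
    allele_variants: Iterable[VariantRecord], model: GeneModel
) -> tuple[bool, str]:
    """True with a reason when the allele cannot keep a full-length ORF."""
    for r in allele_variants:
        if r.effect == "frame_disrupting":
            return True, (
                f"frame-disrupting {r.kind} of {r.length} bp at position {r.ref_pos}"
            )
        if r.kind == "deletion" and _spans_splice_junction(r, model):
            return True, (
                f"deletion at position {r.ref_pos} removes an exon/intron junction"
            )
    return False, ""


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "allele_id", "ref_pos", "kind", "ref_bases", "alt_bases",
    "region", "effect", "domain",
]


def write_variants_tsv(table: VariantTable, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {c: getattr(r, c) for c in TSV_COLUMNS}
            for r in table
        ],
        columns=TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_variants_vcf(
    table: VariantTable, consensus: str, path: str | Path,
    contig: str = "consensus",
) -> None:
    """Minimal VCF 4.2 with the consensus as the reference contig.

    Indels are written with an anchor base (previous reference base; the
    following base when the event starts at position 1).
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={len(consensus)}>",
        '##INFO=<ID=ALLELE,Number=1,Type=String,Description="Allele carrying the variant">',
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for r in table:
        if r.kind == "SNP":
            pos, ref, alt = r.ref_pos, r.ref_bases, r.alt_bases
        elif r.kind == "deletion":
            if r.ref_pos > 1:
                pos = r.ref_pos - 1
                anchor = consensus[pos - 1]
                ref, alt = anchor + r.ref_bases, anchor
            else:
                pos = 1
                anchor = consensus[r.end]
                ref, alt = r.ref_bases + anchor, anchor
        else:  # insertion after ref_pos
            if r.ref_pos >= 1:
                pos = r.ref_pos
                anchor = consensus[pos - 1]
                ref, alt = anchor, anchor + r.alt_bases
            else:
                pos = 1
                anchor = consensus[0]
                ref, alt = anchor, r.alt_bases + anchor
        info = f"ALLELE={r.allele_id};EFFECT={r.effect}"
        lines.append(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")
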
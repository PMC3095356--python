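"""Sequence I/O, near-identical multiple alignment, and consensus construction.

An allelic series of a single gene is near-identical (>97% pairwise identity
for true alleles; paralogs from the same cluster sit around 83–88%).  For such
inputs a center-star strategy — every sequence aligned pairwise to a designated
center with an affine-gap global aligner, insertions merged into shared
columns — recovers the optimal-scoring columns in practice, without an external
MSA tool.  The consensus of the aligned alleles serves as the reference
coordinate system for every downstream statistic (1-based, ungapped consensus
positions).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")
VALID_ROLES = ("allele", "paralog", "reference")
VALID_PLOIDY = ("hexaploid", "tetraploid", "unknown")

GAP = "-"


class SequenceFormatError(ValueError):
    """Raised when an input sequence file violates the format contract."""


@dataclass
class AlleleSequence:
    """One ungapped DNA sequence with screening metadata.

    role distinguishes true alleles from cluster paralogs and a designated
    reference; ploidy_group carries the hexaploid/tetraploid grouping used by
    the diversity summaries.
    """

    id: str
    bases: str
    role: str = "allele"
    ploidy_group: str = "unknown"
    origin: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.bases:
            raise ValueError(f"{self.id}: empty sequence")
        self.bases = self.bases.upper().replace("U", "T")
        for i, b in enumerate(self.bases):
            if b not in VALID_BASES:
                raise SequenceFormatError(
                    f"{self.id}: invalid character {b!r} at position {i + 1}"
                )
        if self.role not in VALID_ROLES:
            raise ValueError(f"{self.id}: unknown role {self.role!r}")
        if self.ploidy_group not in VALID_PLOIDY:
            raise ValueError(f"{self.id}: unknown ploidy_group {self.ploidy_group!r}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlleleAlignment:
    """Gapped rows over a shared column coordinate system.

    Invariant: all rows have equal length and de-gapping a row reproduces the
    input sequence byte-for-byte.  ``ref_id`` names the row whose ungapped
    1-based positions define the reference coordinate system (usually the
    consensus row added by :func:`add_reference_row`).
    """

    rows: list[tuple[str, str]]
    ref_id: str | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        self._index = {}
        for i, (rid, _) in enumerate(self.rows):
            if rid in self._index:
                raise ValueError(f"duplicate row id {rid!r}")
            self._index[rid] = i
        if self.ref_id is not None and self.ref_id not in self._index:
            raise KeyError(f"ref_id {self.ref_id!r} not among rows")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        try:
            return self.rows[self._index[rid]][1]
        except KeyError:
            raise KeyError(f"no row named {rid!r}") from None

    def __contains__(self, rid: str) -> bool:
        return rid in self._index

    def degapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def subset(self, ids: Sequence[str]) -> "AlleleAlignment":
        return AlleleAlignment(
            rows=[(rid, self.row(rid)) for rid in ids],
            ref_id=self.ref_id if self.ref_id in ids else None,
        )


@dataclass
class ConsensusProfile:
    """Per-column base counts plus the majority-rule consensus string.

    ``tie_columns`` lists 0-based columns where the maximal non-gap base count
    was attained by more than one base; ties are broken lexicographically
    (A<C<G<T) so the consensus is deterministic.  A column whose gap count
    strictly exceeds every base count gets a gap consensus and therefore no
    reference position.
    """

    counts: list[dict[str, int]]
    consensus: str
    tie_columns: list[int]

    @property
    def consensus_ungapped(self) -> str:
        return self.consensus.replace(GAP, "")


# ---------------------------------------------------------------------------
# FASTA / metadata I/O
# ---------------------------------------------------------------------------

def _parse_header_metadata(description: str) -> dict[str, str]:
    """Extract key=value tokens from a FASTA description line."""
    meta: dict[str, str] = {}
    for token in description.split()[1:]:
        if "=" in token:
            k, v = token.split("=", 1)
            meta[k] = v
    return meta


def read_fasta(path: str | Path, metadata_tsv: str | Path | None = None,
               allow_gaps: bool = False) -> list[AlleleSequence]:
    """Read a multi-FASTA into :class:`AlleleSequence` records.

    Metadata (role, ploidy_group, origin) is taken from ``key=value`` tokens in
    the header and/or a sidecar TSV with columns id/role/ploidy_group/origin
    (TSV wins on conflict).  Bases are upper-cased and U is normalised to T.
    Non-IUPAC characters are rejected with a position report.
    """
    path = Path(path)
    sidecar: dict[str, dict[str, str]] = {}
    if metadata_tsv is not None:
        import csv

        with open(metadata_tsv, newline="") as fh:
            for line in csv.DictReader(fh, delimiter="\t"):
                sidecar[line["id"]] = line
    records: list[AlleleSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceFormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        meta = _parse_header_metadata(rec.description)
        meta.update({k: v for k, v in sidecar.get(rec.id, {}).items() if k != "id" and v})
        bases = str(rec.seq)
        if allow_gaps:
            bases = bases.replace(GAP, "")
        records.append(
            AlleleSequence(
                id=rec.id,
                bases=bases,
                role=meta.get("role", "allele"),
                ploidy_group=meta.get("ploidy_group", "unknown"),
                origin=meta.get("origin", ""),
            )
        )
    if not records:
        raise SequenceFormatError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: Iterable[AlleleSequence], path: str | Path,
                with_metadata: bool = True) -> None:
    """Write sequences as 60-column wrapped FASTA (UTF-8, LF endings)."""
    recs = []
    for s in sequences:
        desc = (
            f"role={s.role} ploidy_group={s.ploidy_group}"
            + (f" origin={s.origin}" if s.origin else "")
            if with_metadata
            else ""
        )
        recs.append(SeqRecord(Seq(s.bases), id=s.id, description=desc))
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(recs, fh, "fasta")


def write_alignment_fasta(alignment: AlleleAlignment, path: str | Path) -> None:
    recs = [SeqRecord(Seq(row), id=rid, description="") for rid, row in alignment.rows]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_prealigned_fasta(path: str | Path, ref_id: str | None = None) -> AlleleAlignment:
    """Ingest a user-supplied alignment FASTA ('-' gaps) and validate it."""
    rows: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        for i, b in enumerate(seq):
            if b not in VALID_BASES and b != GAP:
                raise SequenceFormatError(
                    f"{rec.id}: invalid character {b!r} at column {i + 1}"
                )
        rows.append((rec.id, seq))
    return AlleleAlignment(rows=rows, ref_id=ref_id)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

DEFAULT_ALIGN_PARAMS = {"match": 1, "mismatch": -2, "gap_open": -8, "gap_extend": -1}


def _make_aligner(params: Mapping[str, float]) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params["match"]
    aligner.mismatch_score = params["mismatch"]
    # open_gap_score applies to the first gap position, so open+extend is the
    # cost of a length-1 gap under the (open, extend) convention used here.
    aligner.open_gap_score = params["gap_open"] + params["gap_extend"]
    aligner.extend_gap_score = params["gap_extend"]
    return aligner


def pairwise_align(a: str, b: str, params: Mapping[str, float] | None = None
                   ) -> tuple[str, str, float]:
    """Global affine-gap alignment of two sequences; returns gapped strings."""
    params = dict(DEFAULT_ALIGN_PARAMS, **(params or {}))
    aligner = _make_aligner(params)
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb, aln.score


def _pairwise_identity(a: str, b: str) -> float:
    ga, gb, _ = pairwise_align(a, b)
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != GAP)
    return matches / max(len(a), len(b))


def align_near_identical(
    sequences: Sequence[AlleleSequence],
    params: Mapping[str, float] | None = None,
    center_id: str | None = None,
) -> AlleleAlignment:
    """Center-star multiple alignment for near-identical sequences.

    Every sequence is globally aligned to the center (a ``role=reference``
    sequence if present, else the first), and the per-center-position
    insertions are merged into shared columns.  Deterministic given inputs and
    parameters.  Intended for allelic series; a warning is emitted when a pair
    falls below 80% identity to the center.
    """
    if len(sequences) == 0:
        raise ValueError("no sequences to align")
    if len(sequences) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    ids = [s.id for s in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")

    if center_id is None:
        refs = [s for s in sequences if s.role == "reference"]
        center = refs[0] if refs else sequences[0]
    else:
        center = next(s for s in sequences if s.id == center_id)

    max_len = max(len(s) for s in sequences)
    min_len = min(len(s) for s in sequences)
    if (max_len - min_len) / max_len > 0.25:
        warnings.warn(
            "sequence lengths differ by >25%; center-star alignment may be poor",
            stacklevel=2,
        )

    L = len(center)
    # per sequence: inserted bases after having consumed p center bases
    # (p in 0..L) and the aligned character at each center position.
    per_seq_ins: dict[str, dict[int, str]] = {}
    per_seq_chars: dict[str, list[str]] = {}
    for s in sequences:
        if s.id == center.id:
            continue
        gc, gs, _ = pairwise_align(center.bases, s.bases, params)
        ident = sum(1 for x, y in zip(gc, gs) if x == y and x != GAP) / max_len
        if ident < 0.80:
            warnings.warn(
                f"pairwise identity of {s.id} to center {center.id} is "
                f"{ident:.1%} (<80%)",
                stacklevel=2,
            )
        ins: dict[int, str] = {}
        chars: list[str] = []
        p = 0
        for x, y in zip(gc, gs):
            if x == GAP:
                ins[p] = ins.get(p, "") + y
            else:
                chars.append(y)
                p += 1
        per_seq_ins[s.id] = ins
        per_seq_chars[s.id] = chars

    slot = [0] * (L + 1)
    for ins in per_seq_ins.values():
        for p, bases in ins.items():
            slot[p] = max(slot[p], len(bases))

    def build_row(chars: Sequence[str], ins: Mapping[int, str]) -> str:
        parts: list[str] = []
        for p in range(L + 1):
            if slot[p]:
                own = ins.get(p, "")
                parts.append(own + GAP * (slot[p] - len(own)))
            if p < L:
                parts.append(chars[p])
        return "".join(parts)

    rows: list[tuple[str, str]] = []
    for s in sequences:
        if s.id == center.id:
            rows.append((s.id, build_row(list(center.bases), {})))
        else:
            rows.append((s.id, build_row(per_seq_chars[s.id], per_seq_ins[s.id])))
    aln = AlleleAlignment(rows=rows, ref_id=center.id)
    for s in sequences:
        assert aln.degapped(s.id) == s.bases, f"round-trip failed for {s.id}"
    return aln


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def build_consensus(
    alignment: AlleleAlignment,
    include_ids: Sequence[str] | None = None,
    roles: Mapping[str, str] | None = None,
    include_roles: Sequence[str] = ("allele",),
) -> ConsensusProfile:
    """Majority-rule consensus over selected rows.

    Selection: explicit ``include_ids`` wins; otherwise, when a ``roles``
    mapping is given, rows whose role is in ``include_roles``; otherwise all
    rows.  N is treated as missing and never counted.  A column is gap in the
    consensus only when gaps strictly outnumber every base.
    """
    if include_ids is None:
        if roles is not None:
            include_ids = [rid for rid in alignment.ids
                           if roles.get(rid, "allele") in include_roles]
        else:
            include_ids = alignment.ids
    if len(include_ids) < 2:
        raise ValueError("consensus needs at least 2 selected rows")
    selected = [alignment.row(rid) for rid in include_ids]

    counts: list[dict[str, int]] = []
    cons: list[str] = []
    ties: list[int] = []
    for col in range(alignment.length):
        c = Counter(row[col] for row in selected)
        c.pop("N", None)
        counts.append(dict(c))
        gap_n = c.get(GAP, 0)
        base_counts = {b: n for b, n in c.items() if b != GAP}
        if not base_counts:
            cons.append(GAP)
            continue
        best = max(base_counts.values())
        winners = sorted(b for b, n in base_counts.items() if n == best)
        if gap_n > best:
            cons.append(GAP)
            continue
        if len(winners) > 1:
            ties.append(col)
        cons.append(winners[0])
    return ConsensusProfile(counts=counts, consensus="".join(cons), tie_columns=ties)


def add_reference_row(alignment: AlleleAlignment, gapped: str,
                      ref_id: str = "consensus") -> AlleleAlignment:
    """Return a new alignment with ``gapped`` prepended as the reference row."""
    if len(gapped) != alignment.length:
        raise ValueError("reference row length does not match alignment")
    if ref_id in alignment:
        raise ValueError(f"row {ref_id!r} already present")
    return AlleleAlignment(rows=[(ref_id, gapped)] + list(alignment.rows), ref_id=ref_id)


# ---------------------------------------------------------------------------
# Coordinate maps
# ---------------------------------------------------------------------------

def column_maps(alignment: AlleleAlignment, ref_id: str | None = None
                ) -> tuple[list[tuple[int, bool]], dict[int, int]]:
    """Column <-> 1-based reference-position maps for the reference row.

    Returns ``(col_to_refpos, refpos_to_col)``.  ``col_to_refpos[c]`` is
    ``(pos, is_insertion)``: for reference-base columns, the 1-based ungapped
    position and False; for reference-gap columns, the nearest preceding
    reference position (0 before the first base) and True.
    """
    ref_id = ref_id or alignment.ref_id
    if ref_id is None:
        raise ValueError("no reference row designated")
    ref_row = alignment.row(ref_id)
    col_to_refpos: list[tuple[int, bool]] = []
    refpos_to_col: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref_row):
        if ch == GAP:
            col_to_refpos.append((pos, True))
        else:
            pos += 1
            col_to_refpos.append((pos, False))
            refpos_to_col[pos] = col
    return col_to_refpos, refpos_to_col
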
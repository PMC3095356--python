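"""Exon/intron gene structure and the CC–NBS–interspacer–LRR domain partition.

The gene studied here has two exons separated by a 200 bp intron; the spliced
coding sequence is 4242 bp and is partitioned into a coiled-coil region
(474 bp), a nucleotide-binding site region (1062 bp), an interspacer (198 bp)
and 28 leucine-rich repeats (2508 bp total).  All genomic intervals are
1-based and inclusive, in reference (consensus) coordinates; domain intervals
live in 1-based CDS coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

Interval = tuple[int, int]

DEFAULT_CDS_LENGTH = 4242
DEFAULT_INTRON_LENGTH = 200
DEFAULT_EXON1_CDS = 966  # junction placement is configuration; total CDS is fixed
DEFAULT_DOMAIN_LENGTHS = {"CC": 474, "NBS": 1062, "interspacer": 198, "LRR": 2508}


@dataclass
class GeneModel:
    """Sorted, non-overlapping exon intervals plus the implied introns."""

    exons: list[Interval]
    introns: list[Interval] = field(default_factory=list)
    cds_frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = 0
        for a, b in self.exons:
            if a < 1 or b < a:
                raise ValueError(f"bad exon interval ({a},{b})")
            if a <= prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = b
        if not self.introns:
            self.introns = [
                (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
                for i in range(len(self.exons) - 1)
            ]
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length {self.cds_length} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def region_of(self, ref_pos: int) -> str:
        """'exonic', 'intronic' or 'noncoding' for a 1-based reference position."""
        for a, b in self.exons:
            if a <= ref_pos <= b:
                return "exonic"
        for a, b in self.introns:
            if a <= ref_pos <= b:
                return "intronic"
        return "noncoding"

    def ref_to_cds(self, ref_pos: int) -> int | None:
        """1-based CDS position of a reference position, None outside exons."""
        cds = 0
        for a, b in self.exons:
            if ref_pos < a:
                return None
            if ref_pos <= b:
                return cds + (ref_pos - a + 1)
            cds += b - a + 1
        return None

    def cds_to_ref(self, cds_pos: int) -> int:
        if cds_pos < 1 or cds_pos > self.cds_length:
            raise ValueError(f"CDS position {cds_pos} out of range")
        cds = 0
        for a, b in self.exons:
            n = b - a + 1
            if cds_pos <= cds + n:
                return a + (cds_pos - cds - 1)
            cds += n
        raise AssertionError("unreachable")


@dataclass
class DomainMap:
    """Ordered named intervals tiling the CDS without overlap or holes."""

    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("empty domain map")
        expected = 1
        for name, a, b in self.intervals:
            if a != expected or b < a:
                raise ValueError(
                    f"domain {name} interval ({a},{b}) leaves a hole or overlap "
                    f"(expected start {expected})"
                )
            expected = b + 1
        self.cds_length = expected - 1

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.intervals]

    def interval(self, name: str) -> Interval:
        for n, a, b in self.intervals:
            if n == name:
                return (a, b)
        raise KeyError(f"no domain named {name!r}")

    def collapsed(self) -> "DomainMap":
        """Collapse LRR_1..LRR_28 into a single LRR interval (top-level view)."""
        out: list[tuple[str, int, int]] = []
        for name, a, b in self.intervals:
            base = name.split("_")[0]
            if out and out[-1][0] == base:
                out[-1] = (base, out[-1][1], b)
            else:
                out.append((base, a, b))
        return DomainMap([tuple(x) for x in out])


def default_gene_model(exon1_cds: int = DEFAULT_EXON1_CDS,
                       cds_length: int = DEFAULT_CDS_LENGTH,
                       intron_length: int = DEFAULT_INTRON_LENGTH) -> GeneModel:
    """Two exons separated by one intron; defaults give a 4442 bp gene."""
    e1 = (1, exon1_cds)
    intron = (exon1_cds + 1, exon1_cds + intron_length)
    e2 = (intron[1] + 1, intron[1] + (cds_length - exon1_cds))
    return GeneModel(exons=[e1, e2])


def default_domain_map(split_lrr: bool = False, n_lrr: int = 28) -> DomainMap:
    """CC, NBS, interspacer and LRR laid contiguously with the default lengths.

    With ``split_lrr`` the LRR region is cut into ``n_lrr`` near-equal slices
    LRR_1..LRR_n.  Those internal boundaries are approximate: only the four
    top-level domain lengths are fixed by the gene's architecture; individual
    repeat boundaries should be supplied by the user when they matter.
    """
    intervals: list[tuple[str, int, int]] = []
    start = 1
    for name in ("CC", "NBS", "interspacer"):
        ln = DEFAULT_DOMAIN_LENGTHS[name]
        intervals.append((name, start, start + ln - 1))
        start += ln
    lrr_len = DEFAULT_DOMAIN_LENGTHS["LRR"]
    if not split_lrr:
        intervals.append(("LRR", start, start + lrr_len - 1))
    else:
        base, rem = divmod(lrr_len, n_lrr)
        for i in range(n_lrr):
            ln = base + (1 if i < rem else 0)
            intervals.append((f"LRR_{i + 1}", start, start + ln - 1))
            start += ln
        start -= 0
    return DomainMap(intervals)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def splice_cds(sequence: str, model: GeneModel) -> str:
    """Concatenate exon subsequences (the coding sequence, intron excluded)."""
    if model.span[1] > len(sequence):
        raise ValueError(
            f"gene model extends to {model.span[1]} but sequence is {len(sequence)} bp"
        )
    return "".join(sequence[a - 1: b] for a, b in model.exons)


def domain_of(cds_position: int, domain_map: DomainMap) -> str:
    """Domain label containing a 1-based CDS position (inclusive intervals)."""
    if cds_position < 1 or cds_position > domain_map.cds_length:
        raise ValueError(
            f"CDS position {cds_position} outside 1..{domain_map.cds_length}"
        )
    for name, a, b in domain_map.intervals:
        if a <= cds_position <= b:
            return name
    raise AssertionError("unreachable: domain map tiles the CDS")


def codon_at(cds_position: int, cds_length: int | None = None) -> tuple[int, int]:
    """(1-based codon index, offset 1..3 within the codon) of a CDS position."""
    if cds_position < 1:
        raise ValueError(f"CDS position {cds_position} out of range")
    if cds_length is not None and cds_position > cds_length:
        raise ValueError(f"CDS position {cds_position} exceeds CDS length {cds_length}")
    return ((cds_position + 2) // 3, (cds_position - 1) % 3 + 1)


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def model_to_config(model: GeneModel, domains: DomainMap) -> dict:
    return {
        "exons": [list(e) for e in model.exons],
        "introns": [list(i) for i in model.introns],
        "domains": [{"name": n, "start": a, "end": b} for n, a, b in domains.intervals],
        "coordinates": "1-based inclusive",
    }


def model_from_config(cfg: dict) -> tuple[GeneModel, DomainMap]:
    model = GeneModel(
        exons=[tuple(e) for e in cfg["exons"]],
        introns=[tuple(i) for i in cfg.get("introns", [])],
    )
    domains = DomainMap([(d["name"], d["start"], d["end"]) for d in cfg["domains"]])
    return model, domains


def load_gene_config(path: str | Path) -> tuple[GeneModel, DomainMap]:
    """Load a gene-model + domain-map config from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return model_from_config(cfg)


def save_gene_config(model: GeneModel, domains: DomainMap, path: str | Path) -> None:
    path = Path(path)
    cfg = model_to_config(model, domains)
    with open(path, "w", newline="\n") as fh:
        if path.suffix == ".json":
            json.dump(cfg, fh, indent=2)
            fh.write("\n")
        else:
            yaml.safe_dump(cfg, fh, sort_keys=False)
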
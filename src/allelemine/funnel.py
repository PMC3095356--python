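"""Accession screening funnel: phenotype → marker → known-allele exclusion →
candidate selection → sequencing outcome, with per-country summarisation.

The funnel mirrors a gene-bank allele-mining campaign: a geographically
diverse accession panel is phenotyped against a panel of pathogen isolates,
accessions with any resistance are genotyped with a locus-presence STS marker
(946 bp diagnostic amplicon), carriers of already-known functional alleles
are excluded, fully resistant accessions become candidates, and candidate
sequences are classified against the consensus and the panel of known
susceptible variants.

Two distinct phenotype rules apply at different stages: intermediate
resistance (IR) is enough to enter molecular screening, but candidacy for
allele isolation requires full resistance (R) to at least one isolate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

PHENOTYPES = ("R", "IR", "IS", "S")
MARKER_STATES = ("present", "absent", "untested")
SEQ_STATUS = ("obtained", "failed", "untested")
SEQ_CLASSES = ("consensus_identical", "known_susceptible_variant", "novel", "none")

STAGE_NAMES = (
    "total",
    "resistant_or_intermediate",
    "haplotype_present",
    "no_known_allele",
    "candidate",
    "sequence_obtained",
)


@dataclass
class AccessionRecord:
    """One gene-bank accession and its screening results."""

    id: str
    origin: str
    phenotypes: dict[str, str]  # isolate name -> R/IR/IS/S
    haplotype_marker: str = "untested"
    known_allele_hits: frozenset[str] = frozenset()
    sequence_status: str = "untested"
    sequence_class: str = "none"
    stages: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for iso, ph in self.phenotypes.items():
            if ph not in PHENOTYPES:
                raise ValueError(f"{self.id}: bad phenotype {ph!r} for isolate {iso}")
        if self.haplotype_marker not in MARKER_STATES:
            raise ValueError(f"{self.id}: bad marker state {self.haplotype_marker!r}")
        if self.sequence_status not in SEQ_STATUS:
            raise ValueError(f"{self.id}: bad sequence status {self.sequence_status!r}")
        if self.sequence_class not in SEQ_CLASSES:
            raise ValueError(f"{self.id}: bad sequence class {self.sequence_class!r}")
        self.known_allele_hits = frozenset(self.known_allele_hits)


@dataclass
class MarkerAssay:
    """An STS presence/absence PCR assay defined by its primer pair."""

    name: str
    forward: str
    reverse: str
    expected_length: int
    max_mismatches: int = 0
    length_tolerance: float = 0.25  # fractional window around expected_length

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if not p or any(b not in "ACGTN" for b in p.upper()):
                raise ValueError(f"{self.name}: malformed primer {p!r}")
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()
        if self.expected_length <= max(len(self.forward), len(self.reverse)):
            raise ValueError(f"{self.name}: expected amplicon shorter than primers")


@dataclass
class FunnelReport:
    """Per-country stage counts plus a totals row (monotone along the funnel)."""

    table: pd.DataFrame  # index: country, columns: STAGE_NAMES

    def __post_init__(self) -> None:
        t = self.table
        for i in range(1, len(STAGE_NAMES)):
            bad = t[STAGE_NAMES[i]] > t[STAGE_NAMES[i - 1]]
            if bad.any():
                raise ValueError(
                    f"funnel counts not monotone for {list(t.index[bad])}"
                )

    @property
    def totals(self) -> tuple[int, ...]:
        return tuple(int(x) for x in self.table.loc["Total", list(STAGE_NAMES)])


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _site_matches(template: str, primer: str, start: int, max_mm: int) -> bool:
    mm = 0
    for a, b in zip(template[start: start + len(primer)], primer):
        if a != b and a != "N" and b != "N":
            mm += 1
            if mm > max_mm:
                return False
    return True


def _find_sites(template: str, primer: str, max_mm: int) -> list[int]:
    n, m = len(template), len(primer)
    return [i for i in range(n - m + 1) if _site_matches(template, primer, i, max_mm)]


def insilico_pcr(sequence: str, assay: MarkerAssay) -> int | None:
    """Predicted amplicon length, or None when the assay would not amplify.

    The forward primer is matched on the plus strand and the reverse primer as
    its reverse complement downstream, each with at most ``max_mismatches``
    mismatches; the product length runs from the 5' end of the forward site to
    the 3' end of the reverse site, inclusive, and must fall within the
    assay's tolerance window around the expected length.  The shortest valid
    product from the leftmost forward site is reported.
    """
    template = sequence.upper()
    if any(b not in "ACGTN" for b in template):
        raise ValueError("template contains non-ACGTN characters")
    fwd_sites = _find_sites(template, assay.forward, assay.max_mismatches)
    rev_sites = _find_sites(template, _revcomp(assay.reverse), assay.max_mismatches)
    lo = assay.expected_length * (1 - assay.length_tolerance)
    hi = assay.expected_length * (1 + assay.length_tolerance)
    best: int | None = None
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(assay.reverse)  # exclusive 3' end of reverse site
            if end <= f + len(assay.forward):
                continue
            length = end - f
            if lo <= length <= hi and (best is None or length < best):
                best = length
    return best


# ---------------------------------------------------------------------------
# Stage logic
# ---------------------------------------------------------------------------

def stage_filters(
    records: Iterable[AccessionRecord], isolate_panel: Sequence[str]
) -> list[AccessionRecord]:
    """Annotate records with the six funnel-stage flags.

    Stage chain: any R/IR phenotype → marker presence → no known-allele hit →
    full R to at least one isolate (candidate) → sequence obtained.  Records
    missing a phenotype for any panel isolate are excluded with a warning.
    """
    out: list[AccessionRecord] = []
    for rec in records:
        missing = [iso for iso in isolate_panel if iso not in rec.phenotypes]
        if missing:
            warnings.warn(
                f"accession {rec.id} lacks phenotypes for {missing}; excluded",
                stacklevel=2,
            )
            continue
        phen = [rec.phenotypes[iso] for iso in isolate_panel]
        s2 = any(p in ("R", "IR") for p in phen)
        s3 = s2 and rec.haplotype_marker == "present"
        s4 = s3 and not rec.known_allele_hits
        s5 = s4 and any(p == "R" for p in phen)
        s6 = s5 and rec.sequence_status == "obtained"
        stages = dict(
            zip(
                STAGE_NAMES,
                (True, s2, s3, s4, s5, s6),
            )
        )
        out.append(replace(rec, stages=stages))
    return out


def summarize_funnel(records: Sequence[AccessionRecord]) -> FunnelReport:
    """Per-country stage counts with a totals row (column sums)."""
    countries = sorted({r.origin for r in records})
    data = {}
    for country in countries:
        sub = [r for r in records if r.origin == country]
        data[country] = [sum(1 for r in sub if r.stages.get(s, False)) for s in STAGE_NAMES]
    order = sorted(countries, key=lambda c: (-data[c][0], c))
    df = pd.DataFrame(
        [data[c] for c in order], index=order, columns=list(STAGE_NAMES), dtype=int
    )
    df.loc["Total"] = df.sum() if len(df) else [0] * len(STAGE_NAMES)
    df.index.name = "country"
    return FunnelReport(table=df)


def known_allele_tally(records: Sequence[AccessionRecord]) -> dict[str, int]:
    """How many marker-positive accessions carry each known allele."""
    tally: dict[str, int] = {}
    for r in records:
        if not r.stages.get("haplotype_present", False):
            continue
        for allele in sorted(r.known_allele_hits):
            tally[allele] = tally.get(allele, 0) + 1
    return dict(sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])))


# ---------------------------------------------------------------------------
# Sequencing outcome classification
# ---------------------------------------------------------------------------

def classify_sequenced(
    allele_bases: str,
    consensus: str,
    known_variant_panel: Mapping[str, str],
) -> str:
    """Classify an obtained sequence against the consensus and known variants.

    consensus_identical: no variants vs the consensus.
    known_susceptible_variant: variant set exactly matches one panel entry
    (panel entries are given as full sequences).
    novel: anything else.
    """
    from .io_alignment import AlleleSequence, align_near_identical
    from .variants import call_variants

    def variant_key(seq: str) -> frozenset:
        if seq == consensus:
            return frozenset()
        aln = align_near_identical(
            [
                AlleleSequence("__ref", consensus, role="reference"),
                AlleleSequence("__query", seq),
            ]
        )
        table = call_variants(aln, "__query", "__ref")
        return frozenset((r.ref_pos, r.kind, r.ref_bases, r.alt_bases) for r in table)

    query = variant_key(allele_bases)
    if not query:
        return "consensus_identical"
    for _, panel_seq in sorted(known_variant_panel.items()):
        if variant_key(panel_seq) == query:
            return "known_susceptible_variant"
    return "novel"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_accession_tsv(path: str | Path, isolate_panel: Sequence[str]
                       ) -> list[AccessionRecord]:
    """Read the accession table.

    Required columns: id, origin, pheno_<isolate> for every panel isolate,
    haplotype_marker, known_allele_hits (comma-separated, may be empty),
    sequence_status, sequence_class.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        hits = frozenset(x for x in row.get("known_allele_hits", "").split(",") if x)
        records.append(
            AccessionRecord(
                id=row["id"],
                origin=row["origin"],
                phenotypes={iso: row[f"pheno_{iso}"] for iso in isolate_panel
                            if f"pheno_{iso}" in row and row[f"pheno_{iso}"]},
                haplotype_marker=row.get("haplotype_marker", "untested") or "untested",
                known_allele_hits=hits,
                sequence_status=row.get("sequence_status", "untested") or "untested",
                sequence_class=row.get("sequence_class", "none") or "none",
            )
        )
    return records


def write_accession_tsv(records: Sequence[AccessionRecord], path: str | Path,
                        isolate_panel: Sequence[str]) -> None:
    rows = []
    for r in records:
        row = {"id": r.id, "origin": r.origin}
        for iso in isolate_panel:
            row[f"pheno_{iso}"] = r.phenotypes.get(iso, "")
        row.update(
            haplotype_marker=r.haplotype_marker,
            known_allele_hits=",".join(sorted(r.known_allele_hits)),
            sequence_status=r.sequence_status,
            sequence_class=r.sequence_class,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_funnel_tsv(report: FunnelReport, path: str | Path) -> None:
    report.table.to_csv(path, sep="\t", lineterminator="\n")


def write_funnel_json(report: FunnelReport, path: str | Path) -> None:
    payload = {
        "stages": list(STAGE_NAMES),
        "countries": {
            str(c): [int(x) for x in report.table.loc[c]]
            for c in report.table.index
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
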
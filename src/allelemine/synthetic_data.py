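"""Synthetic allelic series, paralog pools and accession panels with truth.

The generator emulates the structure of a resistance-gene allelic series:

* an ancestral consensus gene of 4442 bp — a 4242 bp CDS in two exons
  separated by a 200 bp intron — with no in-frame stop codon;
* alleles derived from it by sparse SNPs (biased toward non-synonymous
  changes, as expected under diversifying selection on the LRR), contiguous
  gene-conversion tracts copied from a donor pool, occasional frame-preserving
  3 bp indels, and rare structure-disrupting deletions (pseudogenes);
* a paralog pool at 83.4–88.3% identity to the consensus;
* an accession screening panel whose per-country funnel margins can either be
  drawn from stage pass probabilities or constrained exactly to a margins
  table.

Every stochastic choice flows from the config seed, and a
:class:`SimulationTruth` record reconstructs each simulated sequence from the
reference exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .funnel import STAGE_NAMES, AccessionRecord
from .gene_model import (
    DEFAULT_CDS_LENGTH,
    DEFAULT_EXON1_CDS,
    DEFAULT_INTRON_LENGTH,
    GeneModel,
    default_gene_model,
)
from .io_alignment import AlleleSequence

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}

# Demo screening-panel margins: per country of origin, the six funnel-stage
# counts of the wheat gene-bank campaign this package models
# (total, R-or-IR, marker-positive, no known allele, candidate, sequenced).
GENEBANK_PANEL_MARGINS: dict[str, tuple[int, int, int, int, int, int]] = {
    "India": (92, 27, 21, 12, 7, 6),
    "China": (90, 15, 8, 6, 2, 2),
    "Nepal": (78, 33, 33, 25, 20, 19),
    "Ethiopia": (63, 10, 8, 8, 4, 3),
    "Mexico": (57, 5, 3, 3, 1, 1),
    "USA": (53, 7, 5, 5, 2, 0),
    "France": (51, 7, 3, 2, 2, 1),
    "Japan": (51, 1, 0, 0, 0, 0),
    "Russia": (38, 6, 3, 1, 0, 0),
    "Argentina": (31, 10, 5, 3, 3, 2),
    "Iraq": (27, 7, 4, 4, 3, 2),
    "Canada": (25, 6, 5, 5, 3, 2),
    "Australia": (23, 7, 3, 2, 2, 1),
    "Tajikistan": (16, 6, 3, 2, 1, 1),
    "Kazakhastan": (9, 2, 1, 0, 0, 0),
    "Azerbaizan": (7, 1, 1, 1, 0, 0),
    "Sudan": (7, 2, 2, 2, 1, 1),
    "Switzerland": (7, 1, 0, 0, 0, 0),
    "Kyrgyztan": (6, 0, 0, 0, 0, 0),
    "Uzbekistan": (2, 1, 1, 0, 0, 0),
}

# Observed breakdown of known functional alleles among marker-positive
# accessions of the same campaign, used when the exact-margin panel needs to
# attribute the known-allele exclusions.
KNOWN_ALLELE_DISTRIBUTION: dict[str, int] = {
    "Pm3c": 17, "Pm3b": 6, "Pm3f": 2, "Pm3e": 2, "Pm3d": 1,
}

# Sequencing outcomes of the 41 obtained sequences: consensus-identical,
# matching the known susceptible variant, or novel.
SEQUENCE_CLASS_DISTRIBUTION: dict[str, int] = {
    "consensus_identical": 8,
    "known_susceptible_variant": 18,
    "novel": 15,
}

DEFAULT_ISOLATES = ("Bgt98275", "BgtSyros", "Bgt96224", "Bgt97011", "Bgt96229", "BgtAsosan")


@dataclass
class SimulationConfig:
    """All simulator knobs; the seed is mandatory for reproducibility."""

    seed: int
    cds_length: int = DEFAULT_CDS_LENGTH
    intron_length: int = DEFAULT_INTRON_LENGTH
    exon1_cds: int = DEFAULT_EXON1_CDS
    n_alleles: int = 8
    snp_mean: float = 6.0                      # Poisson mean SNPs per allele
    nonsynonymous_fraction: float = 0.72       # ≈ Ka/(Ka+Ks) for count ratio ~2.6
    n_conversion_mean: float = 0.8             # Poisson mean tracts per allele
    tract_mean_length: int = 300               # geometric mean tract length
    tract_min_length: int = 50
    indel3_prob: float = 0.12                  # per-allele 3 bp in-frame indel
    pseudogene_prob: float = 0.0
    pseudogene_deletion_length: int = 302      # spans the exon1/intron junction
    n_paralogs: int = 3
    paralog_divergence_band: tuple[float, float] = (0.117, 0.166)

    def __post_init__(self) -> None:
        for p in (self.nonsynonymous_fraction, self.indel3_prob, self.pseudogene_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        lo, hi = self.paralog_divergence_band
        if not 0.0 <= lo <= hi < 1.0:
            raise ValueError("divergence band must lie within [0, 1)")
        if self.cds_length % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")


@dataclass
class TractEvent:
    donor_id: str
    start: int  # 1-based reference coordinates, inclusive
    end: int
    diagnostic_sites: list[int] = field(default_factory=list)  # donor != reference


@dataclass
class SnpEvent:
    position: int  # 1-based reference coordinate
    ref: str
    alt: str
    effect: str  # synonymous / nonsynonymous / intronic (at injection time)


@dataclass
class IndelEvent:
    kind: str      # insertion | deletion
    position: int  # insertion: anchor (after); deletion: first removed base
    bases: str


@dataclass
class AlleleTruth:
    allele_id: str
    snps: list[SnpEvent] = field(default_factory=list)
    tracts: list[TractEvent] = field(default_factory=list)
    indels: list[IndelEvent] = field(default_factory=list)
    pseudogene: bool = False

    def reconstruct(self, reference: str, donors: Mapping[str, str]) -> str:
        """Replay the recorded events on the reference; must equal the output."""
        seq = list(reference)
        for t in self.tracts:
            seq[t.start - 1: t.end] = donors[t.donor_id][t.start - 1: t.end]
        for s in self.snps:
            seq[s.position - 1] = s.alt
        for ev in sorted(self.indels, key=lambda e: e.position, reverse=True):
            if ev.kind == "deletion":
                del seq[ev.position - 1: ev.position - 1 + len(ev.bases)]
            else:
                seq[ev.position: ev.position] = list(ev.bases)
        return "".join(seq)


@dataclass
class SimulationTruth:
    reference: str
    gene_model: GeneModel
    alleles: dict[str, AlleleTruth] = field(default_factory=dict)
    donor_sequences: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Reference and paralogs
# ---------------------------------------------------------------------------

def simulate_reference(config: SimulationConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[AlleleSequence, GeneModel]:
    """Random gene with the configured exon/intron structure and a clean ORF."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_codons = config.cds_length // 3
    codons = []
    # ATG start, no stop until the final codon
    codons.append("ATG")
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(BASES), size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append("TGA")
    cds = "".join(codons)
    protein = str(Seq(cds).translate())
    assert "*" not in protein[:-1], "premature stop in simulated CDS"
    intron = "GT" + "".join(rng.choice(list(BASES), size=config.intron_length - 4)) + "AG"
    genomic = cds[: config.exon1_cds] + intron + cds[config.exon1_cds:]
    model = default_gene_model(config.exon1_cds, config.cds_length, config.intron_length)
    return AlleleSequence("reference", genomic, role="reference"), model


def simulate_paralog(reference: AlleleSequence, config: SimulationConfig,
                     rng: np.random.Generator, name: str = "paralog_1"
                     ) -> AlleleSequence:
    """Substitution-only paralog within the configured divergence band."""
    lo, hi = config.paralog_divergence_band
    frac = rng.uniform(lo, hi)
    n = len(reference.bases)
    k = int(round(frac * n))
    positions = rng.choice(n, size=k, replace=False)
    seq = list(reference.bases)
    for p in positions:
        choices = [b for b in BASES if b != seq[p]]
        seq[p] = choices[rng.integers(len(choices))]
    out = AlleleSequence(name, "".join(seq), role="paralog")
    mismatch = sum(1 for a, b in zip(out.bases, reference.bases) if a != b) / n
    assert lo - 1e-9 <= mismatch <= hi + 1e-9
    return out


# ---------------------------------------------------------------------------
# Allelic series
# ---------------------------------------------------------------------------

def _classify_snp(seq: list[str], model: GeneModel, pos: int, alt: str) -> str:
    region = model.region_of(pos)
    if region != "exonic":
        return "intronic" if region == "intronic" else "not_applicable"
    cds_pos = model.ref_to_cds(pos)
    codon_idx = (cds_pos + 2) // 3
    offset = (cds_pos - 1) % 3
    codon_start_cds = (codon_idx - 1) * 3 + 1
    codon = "".join(seq[model.cds_to_ref(codon_start_cds + k) - 1] for k in range(3))
    mutant = codon[:offset] + alt + codon[offset + 1:]
    return (
        "synonymous"
        if str(Seq(codon).translate()) == str(Seq(mutant).translate())
        else "nonsynonymous"
    )


def simulate_allele_series(
    reference: AlleleSequence,
    paralogs: Sequence[AlleleSequence],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    model: GeneModel | None = None,
    ploidy_groups: Mapping[str, str] | None = None,
    shared_tract: TractEvent | None = None,
    shared_tract_ids: Sequence[str] = (),
) -> tuple[list[AlleleSequence], SimulationTruth]:
    """Derive an allelic series from the reference with recorded ground truth.

    Each allele = reference + conversion tracts copied verbatim from a donor
    + SNPs (which may overwrite tract sites, yielding partially shared
    blocks) + optional in-frame 3 bp indels + optional pseudogene deletion
    spanning the exon1/intron junction.  ``shared_tract`` forces one named
    tract onto the alleles in ``shared_tract_ids`` (used to build
    ploidy-specific block footprints).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    model = model or default_gene_model(
        config.exon1_cds, config.cds_length, config.intron_length
    )
    donors = {p.id: p.bases for p in paralogs}
    truth = SimulationTruth(
        reference=reference.bases, gene_model=model, donor_sequences=dict(donors)
    )
    n_ref = len(reference.bases)
    ploidy_groups = ploidy_groups or {}

    alleles: list[AlleleSequence] = []
    for i in range(config.n_alleles):
        aid = f"allele_{i + 1}"
        at = AlleleTruth(allele_id=aid)
        seq = list(reference.bases)

        # conversion tracts (donor copies)
        wanted: list[TractEvent] = []
        if shared_tract is not None and aid in shared_tract_ids:
            wanted.append(
                TractEvent(shared_tract.donor_id, shared_tract.start, shared_tract.end)
            )
        n_extra = int(rng.poisson(config.n_conversion_mean)) if donors else 0
        for _ in range(n_extra):
            donor_id = sorted(donors)[rng.integers(len(donors))]
            length = max(
                config.tract_min_length,
                int(rng.geometric(1.0 / config.tract_mean_length)),
            )
            length = min(length, n_ref - 1)
            start = int(rng.integers(1, n_ref - length + 1))
            wanted.append(TractEvent(donor_id, start, start + length - 1))
        for t in wanted:
            donor = donors[t.donor_id]
            diag = [
                p
                for p in range(t.start, t.end + 1)
                if donor[p - 1] != reference.bases[p - 1]
            ]
            seq[t.start - 1: t.end] = donor[t.start - 1: t.end]
            at.tracts.append(TractEvent(t.donor_id, t.start, t.end, diag))

        # SNPs, biased toward non-synonymous changes in the CDS
        n_snps = int(rng.poisson(config.snp_mean))
        used = set()
        for _ in range(n_snps):
            want_nonsyn = rng.random() < config.nonsynonymous_fraction
            placed = False
            for _try in range(300):
                pos = int(rng.integers(1, n_ref + 1))
                if pos in used:
                    continue
                current = seq[pos - 1]
                alts = [
                    b for b in BASES if b != current and b != reference.bases[pos - 1]
                ]
                if not alts:
                    continue
                alt = alts[rng.integers(len(alts))]
                effect = _classify_snp(seq, model, pos, alt)
                if effect in ("synonymous", "nonsynonymous") and (
                    (effect == "nonsynonymous") != want_nonsyn
                ):
                    continue
                used.add(pos)
                seq[pos - 1] = alt
                at.snps.append(SnpEvent(pos, reference.bases[pos - 1], alt, effect))
                placed = True
                break
            if not placed:  # pragma: no cover - only under extreme configs
                break

        # in-frame 3 bp indels inside exon 2 (away from splice junctions)
        if rng.random() < config.indel3_prob:
            e2a, e2b = model.exons[-1]
            if rng.random() < 0.5:
                anchor = int(rng.integers(e2a + 3, e2b - 3))
                bases = "".join(rng.choice(list(BASES), size=3))
                at.indels.append(IndelEvent("insertion", anchor, bases))
            else:
                start = int(rng.integers(e2a + 3, e2b - 6))
                at.indels.append(
                    IndelEvent("deletion", start, "".join(seq[start - 1: start + 2]))
                )

        # pseudogene: deletion removing the exon1/intron junction
        if rng.random() < config.pseudogene_prob:
            junction = model.exons[0][1]
            dlen = config.pseudogene_deletion_length
            start = max(2, junction - dlen // 2)
            at.indels.append(
                IndelEvent("deletion", start, "".join(seq[start - 1: start - 1 + dlen]))
            )
            at.pseudogene = True

        for ev in sorted(at.indels, key=lambda e: e.position, reverse=True):
            if ev.kind == "deletion":
                del seq[ev.position - 1: ev.position - 1 + len(ev.bases)]
            else:
                seq[ev.position: ev.position] = list(ev.bases)

        bases = "".join(seq)
        allele = AlleleSequence(
            aid, bases, role="allele", ploidy_group=ploidy_groups.get(aid, "unknown")
        )
        assert at.reconstruct(reference.bases, donors) == bases
        # donor pool for later alleles' tracts: keep substitution-only state
        truth.alleles[aid] = at
        alleles.append(allele)
    return alleles, truth


def simulate_series(config: SimulationConfig) -> tuple[
    AlleleSequence, list[AlleleSequence], list[AlleleSequence], SimulationTruth
]:
    """Convenience wrapper: reference + paralog pool + allelic series."""
    rng = np.random.default_rng(config.seed)
    reference, model = simulate_reference(config, rng)
    paralogs = [
        simulate_paralog(reference, config, rng, name=f"paralog_{k + 1}")
        for k in range(config.n_paralogs)
    ]
    alleles, truth = simulate_allele_series(reference, paralogs, config, rng, model)
    return reference, paralogs, alleles, truth


# ---------------------------------------------------------------------------
# Accession panel
# ---------------------------------------------------------------------------

def simulate_accession_panel(
    margins: Mapping[str, Sequence[int]] | None = None,
    seed: int = 0,
    isolate_panel: Sequence[str] = DEFAULT_ISOLATES,
    known_allele_distribution: Mapping[str, int] | None = None,
    sequence_class_distribution: Mapping[str, int] | None = None,
    n_per_country: Mapping[str, int] | None = None,
    stage_probs: Sequence[float] = (0.2, 0.7, 0.75, 0.6, 0.8),
) -> list[AccessionRecord]:
    """Generate an accession panel, exactly margin-constrained or random.

    Exact mode (``margins`` given): per country the six stage counts are hit
    exactly; the records dropped at the known-allele stage receive allele hits
    following ``known_allele_distribution``, and obtained sequences receive
    classes following ``sequence_class_distribution``.  Random mode draws each
    stage survival independently with ``stage_probs``.
    """
    rng = np.random.default_rng(seed)
    records: list[AccessionRecord] = []

    if margins is not None:
        for country, m in margins.items():
            n, s2, s3, s4, s5, s6 = m
            if not (n >= s2 >= s3 >= s4 >= s5 >= s6 >= 0):
                raise ValueError(
                    f"inconsistent margins for {country}: {tuple(m)} must be non-increasing"
                )
        hit_pool: list[str] = []
        if known_allele_distribution is None:
            known_allele_distribution = KNOWN_ALLELE_DISTRIBUTION
        for allele, count in known_allele_distribution.items():
            hit_pool.extend([allele] * count)
        class_pool: list[str] = []
        if sequence_class_distribution is None:
            sequence_class_distribution = SEQUENCE_CLASS_DISTRIBUTION
        for cls, count in sequence_class_distribution.items():
            class_pool.extend([cls] * count)

        hit_i = cls_i = 0
        iso0 = isolate_panel[0]
        rest = {iso: "S" for iso in isolate_panel[1:]}
        for country, (n, s2, s3, s4, s5, s6) in margins.items():
            for i in range(n):
                rid = f"{country[:3].upper()}{i + 1:04d}"
                if i < s6 or i < s5:
                    phen = {iso0: "R", **rest}
                elif i < s2:
                    phen = {iso0: "IR", **rest}
                else:
                    phen = {iso: "S" for iso in isolate_panel}
                marker = "present" if i < s3 else ("absent" if i < s2 else "untested")
                hits: frozenset[str] = frozenset()
                if s4 <= i < s3:
                    hits = frozenset(
                        {hit_pool[hit_i % len(hit_pool)]} if hit_pool else {"known"}
                    )
                    hit_i += 1
                if i < s6:
                    status = "obtained"
                    cls = class_pool[cls_i % len(class_pool)] if class_pool else "novel"
                    cls_i += 1
                elif i < s5:
                    status, cls = "failed", "none"
                else:
                    status, cls = "untested", "none"
                records.append(
                    AccessionRecord(
                        id=rid,
                        origin=country,
                        phenotypes=phen,
                        haplotype_marker=marker,
                        known_allele_hits=hits,
                        sequence_status=status,
                        sequence_class=cls,
                    )
                )
        return records

    # random mode
    if n_per_country is None:
        raise ValueError("random mode needs n_per_country")
    p2, p3, p4, p5, p6 = stage_probs
    for country, n in n_per_country.items():
        for i in range(n):
            rid = f"{country[:3].upper()}{i + 1:04d}"
            resistant = rng.random() < p2
            fully = resistant and rng.random() < 0.5
            iso0 = isolate_panel[0]
            phen = {iso: "S" for iso in isolate_panel}
            if resistant:
                phen[iso0] = "R" if fully else "IR"
            marker = (
                "present" if (resistant and rng.random() < p3)
                else ("absent" if resistant else "untested")
            )
            hits: frozenset[str] = frozenset()
            if marker == "present" and rng.random() > p4:
                pool = sorted(KNOWN_ALLELE_DISTRIBUTION)
                hits = frozenset({pool[rng.integers(len(pool))]})
            candidate = fully and marker == "present" and not hits
            status = (
                "obtained" if candidate and rng.random() < p6
                else ("failed" if candidate else "untested")
            )
            records.append(
                AccessionRecord(
                    id=rid,
                    origin=country,
                    phenotypes=phen,
                    haplotype_marker=marker,
                    known_allele_hits=hits,
                    sequence_status=status,
                )
            )
    return records
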
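"""Domain-partitioned diversity statistics for an allelic series.

Per region (whole CDS, CC, NBS, interspacer, LRR) and per ploidy group this
module computes the number of polymorphic (segregating) sites, sites per
100 bp, nucleotide diversity π (average pairwise proportion of differing
sites, pairwise deletion), and raw counts of synonymous (Ks) and
non-synonymous (Ka) segregating changes relative to the group consensus, with
equal-weight pathway averaging for codons carrying several changes.

Reported "Ka/Ks" is by default the plain ratio of the two counts — the
convention behind the published summary tables this module mirrors — with a
site-normalized Nei–Gojobori pN/pS (Jukes–Cantor corrected) available as an
explicitly labelled alternative.  Printed values are truncated (floored) to
two decimals, matching the tables; rounding is available as an option.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .gene_model import DomainMap, GeneModel
from .io_alignment import GAP, AlleleAlignment, column_maps

REGION_ORDER = ("CDS", "CC", "NBS", "interspacer", "LRR")


@dataclass
class DiversitySummary:
    """One summary-table row: one group × one region."""

    group: str
    region: str
    aligned_sites: int       # ungapped reference length of the region
    gapped_sites: int        # alignment columns spanned by the region
    polymorphic_sites: int
    per_100bp: float         # against aligned_sites (ungapped denominator)
    per_100bp_gapped: float  # against gapped_sites
    pi: float
    ks_count: int
    ka_count: int
    ratio: float | None      # None when ks_count == 0 (printed as "-")


# ---------------------------------------------------------------------------
# Formatting conventions
# ---------------------------------------------------------------------------

def floor2(x: float) -> float:
    """Truncate to 2 decimals (with a guard against binary representation)."""
    return math.floor(x * 100 + 1e-9) / 100


def round2(x: float) -> float:
    return math.floor(x * 100 + 0.5) / 100


def substitution_ratio(ka_count: int, ks_count: int,
                       mode: str = "floor") -> float | None:
    """Ka/Ks as the plain ratio of counts, truncated to 2 decimals.

    Returns None (rendered "-") when no synonymous changes exist.
    """
    if ka_count < 0 or ks_count < 0:
        raise ValueError("substitution counts must be non-negative")
    if ks_count == 0:
        return None
    r = ka_count / ks_count
    return floor2(r) if mode == "floor" else round2(r)


def per_100bp(count: int, length: int, mode: str = "floor") -> float:
    """Polymorphic sites per 100 bp, truncated to 2 decimals."""
    if length <= 0:
        raise ValueError("length must be positive")
    v = 100.0 * count / length
    return floor2(v) if mode == "floor" else round2(v)


def format_ratio(ratio: float | None) -> str:
    return "-" if ratio is None else f"{ratio:.2f}"


# ---------------------------------------------------------------------------
# Region plumbing
# ---------------------------------------------------------------------------

def _region_intervals(domain_map: DomainMap) -> dict[str, tuple[int, int]]:
    top = domain_map.collapsed()
    out = {"CDS": (1, top.cds_length)}
    for name, a, b in top.intervals:
        out[name] = (a, b)
    return out


def region_columns(
    alignment: AlleleAlignment,
    model: GeneModel,
    cds_interval: tuple[int, int],
    ref_id: str | None = None,
) -> list[int]:
    """Alignment columns of the reference-CDS positions in a CDS interval."""
    _, refpos_to_col = column_maps(alignment, ref_id)
    cols = []
    for cds_pos in range(cds_interval[0], cds_interval[1] + 1):
        ref_pos = model.cds_to_ref(cds_pos)
        cols.append(refpos_to_col[ref_pos])
    return cols


def _gapped_span(
    alignment: AlleleAlignment,
    model: GeneModel,
    cds_interval: tuple[int, int],
    ref_id: str | None = None,
) -> int:
    """Number of alignment columns attributable to the region, insertions included."""
    col_to_refpos, _ = column_maps(alignment, ref_id)
    ref_a = model.cds_to_ref(cds_interval[0])
    ref_b = model.cds_to_ref(cds_interval[1])
    n = 0
    for pos, is_ins in col_to_refpos:
        if ref_a <= pos <= ref_b:
            # skip intron positions; insertion columns inherit their anchor
            if is_ins or model.region_of(pos) == "exonic":
                n += 1
    return n


def _group_matrix(alignment: AlleleAlignment, ids: Sequence[str],
                  cols: Sequence[int]) -> np.ndarray:
    rows = [alignment.row(rid) for rid in ids]
    arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), -1)
    return arr[:, list(cols)]


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def count_polymorphic_sites(
    alignment: AlleleAlignment,
    model: GeneModel,
    cds_interval: tuple[int, int],
    group_ids: Sequence[str],
    ref_id: str | None = None,
) -> int:
    """Segregating sites in a region under complete deletion.

    A column counts when, among group members, at least two distinct non-gap
    non-N bases occur; columns where any member has a gap are excluded.
    """
    if not group_ids:
        raise ValueError("empty group")
    cols = region_columns(alignment, model, cds_interval, ref_id)
    mat = _group_matrix(alignment, group_ids, cols)
    count = 0
    for j in range(mat.shape[1]):
        col = mat[:, j]
        if (col == b"-").any():
            continue
        bases = set(col[col != b"N"].tobytes())
        if len(bases) >= 2:
            count += 1
    return count


def nucleotide_diversity(
    alignment: AlleleAlignment,
    model: GeneModel,
    cds_interval: tuple[int, int],
    group_ids: Sequence[str],
    ref_id: str | None = None,
    estimator: str = "pairwise",
) -> float:
    """π: mean over unordered pairs of (differing sites / compared sites).

    Pairwise deletion: for each pair only columns where both members carry a
    non-gap, non-N base are compared.  ``estimator='pairwise'`` (default)
    averages over the n(n-1)/2 unordered pairs — the standard sample π.
    ``estimator='plugin'`` divides the same pair sum by n² (the expected
    heterozygosity of the observed base frequencies); unlike the sample π it
    is exactly invariant under duplicating the whole panel.
    """
    if len(group_ids) < 2:
        raise ValueError("nucleotide diversity needs at least 2 group members")
    if estimator not in ("pairwise", "plugin"):
        raise ValueError(f"unknown estimator {estimator!r}")
    cols = region_columns(alignment, model, cds_interval, ref_id)
    mat = _group_matrix(alignment, group_ids, cols)
    valid = (mat != b"-") & (mat != b"N")
    total = 0.0
    n = mat.shape[0]
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        compared = int(both.sum())
        if compared == 0:
            continue
        diffs = int(((mat[i] != mat[j]) & both).sum())
        total += diffs / compared
    if estimator == "pairwise":
        return total / (n * (n - 1) / 2)
    return 2.0 * total / (n * n)


def _group_consensus_bases(mat: np.ndarray) -> list[bytes | None]:
    """Majority base per column over non-gap, non-N members (A<C<G<T on ties).

    None marks columns with no usable base.
    """
    out: list[bytes | None] = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        col = col[(col != b"-") & (col != b"N")]
        if col.size == 0:
            out.append(None)
            continue
        uniq, counts = np.unique(col, return_counts=True)
        best = counts.max()
        winners = sorted(u for u, c in zip(uniq, counts) if c == best)
        out.append(winners[0])
    return out


def _codon_pathway_tallies(codon: str, changes: Sequence[tuple[int, str]]
                           ) -> tuple[float, float]:
    """Average (syn, nonsyn) step tallies over all orderings of the changes.

    Each change is (0-based offset within codon, alt base).  Changes are
    applied sequentially with overwrite; every application step is classified
    by comparing the translated codon before and after.  All orderings get
    equal weight.
    """
    if not changes:
        return 0.0, 0.0
    syn_total = nonsyn_total = 0.0
    perms = list(itertools.permutations(range(len(changes))))
    for order in perms:
        state = list(codon)
        for k in order:
            off, alt = changes[k]
            before = str(Seq("".join(state)).translate())
            state[off] = alt
            after = str(Seq("".join(state)).translate())
            if before == after:
                syn_total += 1
            else:
                nonsyn_total += 1
    n = len(perms)
    return syn_total / n, nonsyn_total / n


def count_substitutions(
    alignment: AlleleAlignment,
    model: GeneModel,
    cds_interval: tuple[int, int],
    group_ids: Sequence[str],
    ref_id: str | None = None,
) -> tuple[int, int]:
    """(Ks, Ka): synonymous and non-synonymous segregating-change counts.

    One change per distinct (site, minority base) relative to the group
    consensus; codons carrying several changes are resolved by equal-weight
    pathway averaging, with the summed fractional tallies rounded half-up at
    the end.  Columns with any gap in the group are excluded (complete
    deletion), and the codon background at such columns stays at the group
    consensus of the remaining members.
    """
    if cds_interval[0] % 3 != 1 or cds_interval[1] % 3 != 0:
        raise ValueError(
            f"region {cds_interval} is not codon-aligned within the CDS frame"
        )
    cols = region_columns(alignment, model, cds_interval, ref_id)
    mat = _group_matrix(alignment, group_ids, cols)
    consensus = _group_consensus_bases(mat)
    any_gap = [(mat[:, j] == b"-").any() for j in range(mat.shape[1])]

    syn = nonsyn = 0.0
    n_pos = cds_interval[1] - cds_interval[0] + 1
    for c0 in range(0, n_pos, 3):
        codon_cons = []
        ok = True
        for k in range(3):
            b = consensus[c0 + k]
            if b is None:
                ok = False
                break
            codon_cons.append(b.decode())
        if not ok:
            continue
        changes: list[tuple[int, str]] = []
        for k in range(3):
            j = c0 + k
            if any_gap[j]:
                continue
            col = mat[:, j]
            observed = set(col[(col != b"-") & (col != b"N")].tobytes().decode())
            for base in sorted(observed - {codon_cons[k]}):
                changes.append((k, base))
        s, ns = _codon_pathway_tallies("".join(codon_cons), changes)
        syn += s
        nonsyn += ns
    return int(math.floor(syn + 0.5)), int(math.floor(nonsyn + 0.5))


# ---------------------------------------------------------------------------
# Site-normalized alternative (Nei–Gojobori pN/pS, labelled, non-default)
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _ng_site_fractions(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, non-synonymous) site counts of one codon."""
    syn = 0.0
    aa = str(Seq(codon).translate())
    for k in range(3):
        s_k = 0
        for b in _BASES:
            if b == codon[k]:
                continue
            mutant = codon[:k] + b + codon[k + 1:]
            if str(Seq(mutant).translate()) == aa:
                s_k += 1
        syn += s_k / 3
    return syn, 3 - syn


def site_normalized_ratio(
    consensus_cds_region: str, ks_count: int, ka_count: int
) -> dict:
    """Nei–Gojobori style pN/pS with Jukes–Cantor correction.

    This normalizes the raw change counts by the numbers of synonymous and
    non-synonymous sites in the region's consensus and is NOT the convention
    of the default summary table; results carry an explicit method label.
    """
    if len(consensus_cds_region) % 3 != 0:
        raise ValueError("region length not a codon multiple")
    S = N = 0.0
    for i in range(0, len(consensus_cds_region), 3):
        s, n = _ng_site_fractions(consensus_cds_region[i: i + 3])
        S += s
        N += n
    ps = ks_count / S if S else float("nan")
    pn = ka_count / N if N else float("nan")

    def jc(p: float) -> float:
        if p >= 0.75:
            return float("nan")
        return -0.75 * math.log(1 - 4 * p / 3)

    ds, dn = jc(ps), jc(pn)
    return {
        "method": "nei_gojobori_pn_ps_jc",
        "syn_sites": S,
        "nonsyn_sites": N,
        "pS": ps,
        "pN": pn,
        "dS": ds,
        "dN": dn,
        "dN_dS": (dn / ds) if ds and not math.isnan(ds) and ds > 0 else None,
    }


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

def summarize_table3(
    alignment: AlleleAlignment,
    model: GeneModel,
    domain_map: DomainMap,
    groups: Mapping[str, Sequence[str]],
    ref_id: str | None = None,
    exclude: Sequence[str] = (),
    mode: str = "floor",
) -> list[DiversitySummary]:
    """Group × region diversity table (pseudogenes should be pre-excluded).

    ``groups`` maps group names (e.g. hexaploid/tetraploid) to member row ids;
    a combined row set is added automatically when more than one group is
    given.  Regions are the whole CDS plus the top-level protein domains.
    """
    groups = {g: [i for i in ids if i not in exclude] for g, ids in groups.items()}
    groups = {g: ids for g, ids in groups.items() if len(ids) >= 2}
    if not groups:
        raise ValueError("no group with at least 2 members")
    if len(groups) > 1:
        combined: list[str] = []
        for ids in groups.values():
            combined.extend(i for i in ids if i not in combined)
        groups = dict(groups, combined=combined)

    intervals = _region_intervals(domain_map)
    rows: list[DiversitySummary] = []
    for gname, ids in groups.items():
        for region in REGION_ORDER:
            if region not in intervals:
                continue
            iv = intervals[region]
            aligned = iv[1] - iv[0] + 1
            gapped = _gapped_span(alignment, model, iv, ref_id)
            poly = count_polymorphic_sites(alignment, model, iv, ids, ref_id)
            pi = nucleotide_diversity(alignment, model, iv, ids, ref_id)
            ks, ka = count_substitutions(alignment, model, iv, ids, ref_id)
            rows.append(
                DiversitySummary(
                    group=gname,
                    region=region,
                    aligned_sites=aligned,
                    gapped_sites=gapped,
                    polymorphic_sites=poly,
                    per_100bp=per_100bp(poly, aligned, mode),
                    per_100bp_gapped=per_100bp(poly, gapped, mode) if gapped else 0.0,
                    pi=pi,
                    ks_count=ks,
                    ka_count=ka,
                    ratio=substitution_ratio(ka, ks, mode),
                )
            )
    return rows


TABLE_COLUMNS = [
    "group", "region", "aligned_sites", "gapped_sites", "polymorphic_sites",
    "per_100bp", "per_100bp_gapped", "pi", "ks_count", "ka_count", "ratio",
]


def summaries_to_frame(rows: Sequence[DiversitySummary]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "group": r.group,
                "region": r.region,
                "aligned_sites": r.aligned_sites,
                "gapped_sites": r.gapped_sites,
                "polymorphic_sites": r.polymorphic_sites,
                "per_100bp": f"{r.per_100bp:.2f}",
                "per_100bp_gapped": f"{r.per_100bp_gapped:.2f}",
                "pi": f"{r.pi:.5f}",
                "ks_count": r.ks_count,
                "ka_count": r.ka_count,
                "ratio": format_ratio(r.ratio),
            }
            for r in rows
        ],
        columns=TABLE_COLUMNS,
    )


def write_diversity_tsv(rows: Sequence[DiversitySummary], path: str | Path) -> None:
    summaries_to_frame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
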
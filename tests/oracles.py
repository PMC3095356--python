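"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (plain Python loops, exhaustive
enumeration) kept separate from the library code they check.
"""

from __future__ import annotations

import itertools

from Bio.Seq import Seq


def gotoh_score(a: str, b: str, match: int = 1, mismatch: int = -2,
                gap_open: int = -8, gap_extend: int = -1) -> float:
    """Optimal global affine-gap alignment score by full dynamic programming.

    A gap of length k costs gap_open + k * gap_extend.
    """
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + i * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] + gap_open + gap_extend,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open + gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open + gap_extend,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open + gap_extend,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def alignment_score(row_a: str, row_b: str, match: int = 1, mismatch: int = -2,
                    gap_open: int = -8, gap_extend: int = -1) -> float:
    """Score of a given pairwise alignment under the affine model."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(row_a, row_b):
        if x == "-" and y == "-":
            continue
        if x == "-":
            score += gap_extend + (0 if in_gap_a else gap_open)
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score += gap_extend + (0 if in_gap_b else gap_open)
            in_gap_b, in_gap_a = True, False
        else:
            score += match if x == y else mismatch
            in_gap_a = in_gap_b = False
    return score


def pi_bruteforce(rows: list[str]) -> float:
    """Average over unordered pairs of (differing / compared) sites.

    Pairwise deletion: only columns where both rows have A/C/G/T count.
    """
    n = len(rows)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            diffs = compared = 0
            for x, y in zip(rows[i], rows[j]):
                if x in "ACGT" and y in "ACGT":
                    compared += 1
                    if x != y:
                        diffs += 1
            if compared:
                total += diffs / compared
    return total / (n * (n - 1) / 2)


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def two_change_pathway_oracle(codon: str, c1: tuple[int, str], c2: tuple[int, str]
                              ) -> tuple[float, float]:
    """Average (syn, nonsyn) tallies over the 2 substitution orders of a codon.

    Each change is (0-based offset, alt base); changes are at distinct offsets.
    """
    syn = nonsyn = 0.0
    for first, second in ((c1, c2), (c2, c1)):
        state = list(codon)
        for off, alt in (first, second):
            before = translate("".join(state))
            state[off] = alt
            after = translate("".join(state))
            if before == after:
                syn += 1
            else:
                nonsyn += 1
    return syn / 2, nonsyn / 2


def funnel_recount(records, isolates) -> tuple[int, ...]:
    """Independent brute-force recount of funnel stage totals."""
    t = s2 = s3 = s4 = s5 = s6 = 0
    for r in records:
        phen = [r.phenotypes[i] for i in isolates]
        t += 1
        a2 = any(p in ("R", "IR") for p in phen)
        a3 = a2 and r.haplotype_marker == "present"
        a4 = a3 and len(r.known_allele_hits) == 0
        a5 = a4 and "R" in phen
        a6 = a5 and r.sequence_status == "obtained"
        s2 += a2
        s3 += a3
        s4 += a4
        s5 += a5
        s6 += a6
    return (t, s2, s3, s4, s5, s6)


def enumerate_two_change_cases():
    """All (codon, change1, change2) with the two changes at distinct offsets."""
    bases = "ACGT"
    for codon in map("".join, itertools.product(bases, repeat=3)):
        for o1, o2 in itertools.combinations(range(3), 2):
            for b1 in bases:
                if b1 == codon[o1]:
                    continue
                for b2 in bases:
                    if b2 == codon[o2]:
                        continue
                    yield codon, (o1, b1), (o2, b2)
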
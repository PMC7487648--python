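"""Independent brute-force oracles used by the test suite.

Each function re-derives an expected result by a route deliberately
different from the implementation under test: naive string edits, quadratic
scans, exhaustive enumeration, or textbook dynamic programming.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from scipy.stats import hypergeom

STOPS = {"TAA", "TAG", "TGA"}


def string_edit_oracle(seq: str, variants) -> str:
    """Apply variants right-to-left as plain string replacements."""
    out = seq
    for v in sorted(variants, key=lambda v: -v.pos):
        assert out[v.pos : v.pos + len(v.ref)] == v.ref
        out = out[: v.pos] + v.alt + out[v.pos + len(v.ref) :]
    return out


def quadratic_merge_oracle(primary, additions, excluded_biotypes):
    """O(n^2) pairwise same-strand exonic overlap filter."""

    def overlaps(t1, t2):
        if t1.chrom != t2.chrom or t1.strand != t2.strand:
            return False
        for s1, e1 in t1.exons:
            for s2, e2 in t2.exons:
                if s1 < e2 and s2 < e1:
                    return True
        return False

    merged = [t for t in primary if t.biotype not in excluded_biotypes]
    for addition in additions:
        for tx in addition:
            if not any(overlaps(tx, m) for m in merged):
                merged.append(tx)
    return merged


def brute_force_orfs(seq: str, starts, min_aa: int):
    """Triple-loop ORF scan: every frame, every stop, the 5'-most valid start.

    Returns (frame, start, stop_end) triples; validity of a start for a stop
    is re-checked by scanning every intermediate codon for stops.
    """
    dna = seq.upper().replace("U", "T")
    start_set = {s.upper().replace("U", "T") for s in starts}
    result = []
    for frame in range(3):
        codon_pos = list(range(frame, len(dna) - 2, 3))
        stop_pos = [
            i for i in codon_pos if dna[i : i + 3] in STOPS and "N" not in dna[i : i + 3]
        ]
        prev_end = frame
        for stop in stop_pos:
            candidates = []
            for s in codon_pos:
                if s < prev_end or s >= stop:
                    continue
                if dna[s : s + 3] not in start_set or "N" in dna[s : s + 3]:
                    continue
                if any(
                    dna[k : k + 3] in STOPS for k in range(s, stop, 3)
                ):
                    continue
                candidates.append(s)
            prev_end = stop + 3
            if candidates:
                start = min(candidates)
                if (stop + 3 - start) // 3 - 1 >= min_aa:
                    result.append((frame, start, stop + 3))
    return sorted(result, key=lambda t: t[1])


_B62 = substitution_matrices.load("BLOSUM62")


def gotoh_score(a: str, b: str, open_: float = -11.0, ext: float = -1.0) -> float:
    """Textbook three-matrix affine-gap global alignment score."""
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Y[0, j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + ext, Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + ext, X[i, j - 1] + open_)
    return float(max(M[n, m], X[n, m], Y[n, m]))


# residue (amino acid minus water) atomic compositions: C, H, N, O, S
_RESIDUE_COMP = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 5, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0), "E": (5, 7, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}
_ATOMIC = {"C": 12.0107, "H": 1.00794, "N": 14.0067, "O": 15.9994, "S": 32.065}
WATER_MASS = 2 * _ATOMIC["H"] + _ATOMIC["O"]


def peptide_mass_oracle(pep: str) -> float:
    """Average MW from atomic composition and standard atomic weights."""
    total = WATER_MASS
    for aa in pep:
        c, h, n, o, s = _RESIDUE_COMP[aa]
        total += (
            c * _ATOMIC["C"] + h * _ATOMIC["H"] + n * _ATOMIC["N"]
            + o * _ATOMIC["O"] + s * _ATOMIC["S"]
        )
    return total


def fisher_enumeration_oracle(table) -> float:
    """Two-sided Fisher p by enumerating all tables with the observed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, c1, r1)
    p = 0.0
    for aa in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pa = hypergeom.pmf(aa, n, c1, r1)
        if pa <= p_obs * (1 + 1e-9):
            p += pa
    return min(p, 1.0)


def naive_ward(dmat: np.ndarray):
    """Lance-Williams Ward agglomeration; returns [(merged ids, height), ...].

    New clusters are numbered n, n+1, ... in merge order, matching the scipy
    linkage convention.
    """
    n = dmat.shape[0]
    dd = {(i, j): float(dmat[i, j]) for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges = []
    nxt = n
    while len(active) > 1:
        h, i, j = min(
            (dd[tuple(sorted((i, j)))], i, j)
            for i in active
            for j in active
            if i < j
        )
        merges.append((sorted((i, j)), h))
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = dd[tuple(sorted((i, k)))]
            djk = dd[tuple(sorted((j, k)))]
            dd[(k, nxt) if k < nxt else (nxt, k)] = float(
                np.sqrt(
                    ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * h**2)
                    / (ni + nj + nk)
                )
            )
        sizes[nxt] = ni + nj
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    return merges


def exhaustive_combining(draws, locus, cutoff, alleles, n_samples):
    """Explore every admissible merge order; return the set of reachable fixpoints.

    ``draws`` maps (group id, allele) -> (n_samples, D) arrays; groups start
    as singletons.  A merge of two same-locus groups is admissible when the
    mean Pearson correlation of their draws over all sample x allele slots
    is below the cutoff.  Used on <= 4 transcripts only.
    """

    def pair_mean_r(da, db):
        vals = []
        for al in alleles:
            for s in range(n_samples):
                x, y = da[al][s], db[al][s]
                if np.std(x) == 0 or np.std(y) == 0:
                    continue
                vals.append(np.corrcoef(x, y)[0, 1])
        return np.mean(vals) if vals else np.nan

    def explore(state):
        # state: tuple of (members tuple, {allele: array}) entries
        fixpoints = set()
        any_merge = False
        for i in range(len(state)):
            for j in range(i + 1, len(state)):
                mi, di = state[i]
                mj, dj = state[j]
                if locus[mi[0]] != locus[mj[0]]:
                    continue
                r = pair_mean_r(di, dj)
                if np.isnan(r) or not r < cutoff:
                    continue
                any_merge = True
                merged = (
                    tuple(sorted(mi + mj)),
                    {al: di[al] + dj[al] for al in alleles},
                )
                rest = [state[k] for k in range(len(state)) if k not in (i, j)]
                fixpoints |= explore(tuple(rest + [merged]))
        if not any_merge:
            fixpoints.add(frozenset(m for m, _ in state))
        return fixpoints

    state = tuple(
        ((t,), {al: draws[(t, al)] for al in alleles})
        for t in sorted({t for t, _ in draws})
    )
    return explore(state)
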
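"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition (loops,
enumeration, exact rational arithmetic) and share no code with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import product

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def tom_brute_force(adj: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap from the definition."""
    a = adj.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided Fisher p by enumerating all tables with the margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x):
        return (Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1)))

    obs = table_prob(a)
    p = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        pr = table_prob(x)
        if pr <= obs:
            p += pr
    return p


def hypergeom_upper_tail(k: int, M: int, K: int, N: int) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeometric(M, K, N)."""
    denom = math.comb(M, N)
    total = sum(math.comb(K, x) * math.comb(M - K, N - x)
                for x in range(k, min(K, N) + 1)
                if 0 <= N - x <= M - K)
    return Fraction(total, denom)


def bh_by_hand(pvals):
    """BH step-up from the textbook definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def pooled_t(x, y):
    """Textbook pooled-variance two-sample t and two-sided p."""
    from scipy.stats import t as tdist

    n1, n2 = len(x), len(y)
    v1 = np.var(x, ddof=1)
    v2 = np.var(y, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t = (np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, 2 * tdist.sf(abs(t), n1 + n2 - 2)


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq))


def expand_pattern(consensus: str):
    """Expand X/Y alternatives and N{k} gaps into per-position allowed sets."""
    if "/" in consensus:
        base, alt = consensus.split("/")
        literals = [base, base[:-1] + alt]
    else:
        literals = [consensus]
    out = []
    for lit in literals:
        positions = []
        i = 0
        while i < len(lit):
            ch = lit[i]
            if ch == "N" and i + 1 < len(lit) and lit[i + 1] == "{":
                j = lit.index("}", i)
                positions.extend([None] * int(lit[i + 2:j]))
                i = j + 1
                continue
            positions.append(None if ch == "N" else set(IUPAC[ch]))
            i += 1
        out.append(positions)
    return out


def scan_brute_force(seq: str, consensus: str, max_mm: int, both_strands: bool = True):
    """Window-by-window consensus matching; returns {(offset, strand): mismatches}."""
    seq = seq.upper()
    L = len(seq)
    alternatives = expand_pattern(consensus)
    span = len(alternatives[0])
    found = {}
    strands = [("+", seq)] + ([("-", revcomp(seq))] if both_strands else [])
    for strand, s in strands:
        for i in range(L - span + 1):
            best = None
            for positions in alternatives:
                mm = 0
                for ch, allowed in zip(s[i:i + span], positions):
                    if allowed is not None and ch not in allowed:
                        mm += 1
                        if mm > max_mm:
                            break
                else:
                    if best is None or mm < best:
                        best = mm
            if best is not None:
                offset = i if strand == "+" else L - i - span
                key = (offset, strand)
                if key not in found or best < found[key]:
                    found[key] = best
    return found


def components_bfs(nodes, edges):
    """Connected components by breadth-first search."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        seen.add(start)
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in seen:
                        seen.add(w)
                        comp.add(w)
                        nxt.append(w)
            frontier = nxt
        comps.append(frozenset(comp))
    return set(comps)


def median_of_ratios(mat: np.ndarray) -> np.ndarray:
    """Size factors from the definition, gene by gene."""
    keep = [g for g in range(mat.shape[0]) if all(mat[g] > 0)]
    geo = {g: math.exp(np.mean([math.log(v) for v in mat[g]])) for g in keep}
    return np.array([
        float(np.median([mat[g, s] / geo[g] for g in keep]))
        for s in range(mat.shape[1])
    ])
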
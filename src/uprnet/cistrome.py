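"""Gapped IUPAC consensus scanning and promoter/peak enrichment for UPR CREs.

The five canonical ER-stress cis-regulatory elements are matched as
consensus patterns (not PWMs): ERSE-I (CCAAT-N10-CACG), ERSE-II
(ATTGG-N2-CACG), UPRE-I (TGACGT-GG/A, exact), UPRE-II (GATGACGCGTAC) and
UPRE-III (TCATCG), allowing one mismatch at non-gap positions for all but
UPRE-I.  Enrichment is presence/absence per promoter against a control set
(one-sided Fisher), and positional bias of matches around ChIP peak summits
is tested with a one-sided binomial test against a uniform placement null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import FormatError, ParameterError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: the five canonical UPR CRE consensi with their mismatch allowances
BUILTIN_CRES = {
    "ERSE-I": ("CCAATN{10}CACG", 1),
    "ERSE-II": ("ATTGGN{2}CACG", 1),
    "UPRE-I": ("TGACGTGG/A", 0),
    "UPRE-II": ("GATGACGCGTAC", 1),
    "UPRE-III": ("TCATCG", 1),
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class CREPattern:
    """A compiled gapped consensus.

    ``alternatives`` holds one tuple per literal alternative (e.g. the two
    UPRE-I variants); each element is either a frozenset of allowed bases or
    None for an N-gap position (any base, never a mismatch).
    """

    name: str
    consensus: str
    max_mismatches: int
    alternatives: tuple
    span: int


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _expand(consensus: str) -> list[str]:
    """Expand the trailing X/Y alternative syntax into literal consensi."""
    if "/" in consensus:
        base, alt = consensus.split("/")
        if len(alt) != 1:
            raise FormatError(f"only single-letter terminal alternatives supported: {consensus}")
        return [base, base[:-1] + alt]
    return [consensus]


def _positions(literal: str) -> tuple:
    """Parse one literal consensus (with N{k} gaps) into per-position sets."""
    out = []
    i = 0
    while i < len(literal):
        ch = literal[i]
        if ch == "N" and i + 1 < len(literal) and literal[i + 1] == "{":
            j = literal.index("}", i)
            out.extend([None] * int(literal[i + 2:j]))
            i = j + 1
            continue
        if ch not in IUPAC:
            raise FormatError(f"illegal consensus character {ch!r}")
        out.append(None if ch == "N" else frozenset(IUPAC[ch]))
        i += 1
    return tuple(out)


def compile_cre(name: str, consensus: str, max_mismatches: int) -> CREPattern:
    """Compile a gapped IUPAC consensus with the N{k} gap syntax."""
    alts = tuple(_positions(lit) for lit in _expand(consensus))
    spans = {len(a) for a in alts}
    if len(spans) != 1:
        raise FormatError(f"alternatives of {name} differ in span")
    return CREPattern(name=name, consensus=consensus,
                      max_mismatches=int(max_mismatches),
                      alternatives=alts, span=spans.pop())


def builtin_patterns() -> dict[str, CREPattern]:
    return {name: compile_cre(name, cons, mm) for name, (cons, mm) in BUILTIN_CRES.items()}


@dataclass(frozen=True)
class MotifMatch:
    """One consensus match, in forward-strand coordinates."""

    offset: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class CistromeParams:
    promoter_length: int = 1000
    control_size: int = 201
    summit_flank: int = 250
    central_window: int = 100
    scan_both_strands: bool = True

    def __post_init__(self):
        if self.central_window >= 2 * self.summit_flank:
            raise ParameterError("central_window must be < 2 * summit_flank")


def _encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and any other letter (incl. N) as 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return arr


def _mismatch_counts(enc: np.ndarray, positions: tuple) -> np.ndarray:
    """Mismatches of every window start against one literal alternative.

    An N in the sequence never matches a literal position; gap positions
    never count.
    """
    span = len(positions)
    n = len(enc) - span + 1
    if n <= 0:
        return np.empty(0, dtype=np.int16)
    counts = np.zeros(n, dtype=np.int16)
    for j, allowed in enumerate(positions):
        if allowed is None:
            continue
        ok = np.zeros(5, dtype=bool)
        for b in allowed:
            ok[_BASE_INDEX[b]] = True
        counts += ~ok[enc[j:j + n]]
    return counts


def scan_sequence(seq: str, pattern: CREPattern, both_strands: bool = True) -> list[MotifMatch]:
    """All matches of a compiled consensus in one sequence.

    Reverse-strand matches are reported at their forward-strand start
    offset.  Overlapping matches are all reported; when several alternatives
    match the same window/strand, the lowest mismatch count is kept.
    """
    seq = seq.upper()
    L = len(seq)
    found: dict[tuple[int, str], int] = {}
    strands = [("+", seq)]
    if both_strands:
        strands.append(("-", revcomp(seq)))
    for strand, s in strands:
        enc = _encode(s)
        for positions in pattern.alternatives:
            mm = _mismatch_counts(enc, positions)
            for i in np.nonzero(mm <= pattern.max_mismatches)[0]:
                offset = int(i) if strand == "+" else L - int(i) - pattern.span
                key = (offset, strand)
                val = int(mm[i])
                if key not in found or val < found[key]:
                    found[key] = val
    return [MotifMatch(offset=o, strand=st, mismatches=m)
            for (o, st), m in sorted(found.items())]


def scan_collection(seqs: dict[str, str], pattern: CREPattern,
                    both_strands: bool = True) -> dict[str, list[MotifMatch]]:
    return {name: scan_sequence(s, pattern, both_strands) for name, s in seqs.items()}


@dataclass
class EnrichmentResult:
    pattern: str
    target_with: int
    target_total: int
    control_with: int
    control_total: int
    p: float


def set_enrichment(
    target_seqs: dict[str, str],
    control_seqs: dict[str, str],
    pattern: CREPattern,
    params: CistromeParams = CistromeParams(),
) -> EnrichmentResult:
    """Presence/absence promoter enrichment, one-sided Fisher exact (greater).

    Targets and controls must be disjoint identifier sets.
    """
    if not target_seqs:
        raise ParameterError("empty target set")
    if set(target_seqs) & set(control_seqs):
        raise ParameterError("target and control promoter sets overlap")
    t_with = sum(bool(scan_sequence(s, pattern, params.scan_both_strands))
                 for s in target_seqs.values())
    c_with = sum(bool(scan_sequence(s, pattern, params.scan_both_strands))
                 for s in control_seqs.values())
    table = [[t_with, len(target_seqs) - t_with], [c_with, len(control_seqs) - c_with]]
    p = float(stats.fisher_exact(table, alternative="greater")[1])
    return EnrichmentResult(pattern.name, t_with, len(target_seqs),
                            c_with, len(control_seqs), p)


def draw_control_set(
    background: dict[str, str],
    exclude: set,
    size: int,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Seeded random control promoters drawn from the background universe."""
    pool = sorted(set(background) - set(exclude))
    if len(pool) < size:
        size = len(pool)
    chosen = rng.choice(pool, size=size, replace=False)
    return {g: background[g] for g in chosen}


@dataclass
class CentralityResult:
    pattern: str
    n_windows: int
    n_with_match: int
    n_central: int
    p0: float
    p: float | None
    status: str


def positional_centrality(
    windows: list[str],
    pattern: CREPattern,
    params: CistromeParams = CistromeParams(),
) -> CentralityResult:
    """Summit-centrality of consensus matches in fixed-width peak windows.

    Windows must all have length 2·summit_flank and be centered on the peak
    summit.  Per window the best match (fewest mismatches, then closest to
    center, then leftmost) is taken; the count of best matches whose center
    lies within ``central_window`` of the window center is tested one-sided
    against the uniform-placement null p0.
    """
    L = 2 * params.summit_flank
    if any(len(w) != L for w in windows):
        raise ParameterError(f"all windows must have length {L}")
    span = pattern.span
    center = L / 2.0
    half = params.central_window / 2.0
    n_with = 0
    n_central = 0
    for w in windows:
        matches = scan_sequence(w, pattern, params.scan_both_strands)
        if not matches:
            continue
        n_with += 1
        best = min(matches, key=lambda m: (m.mismatches,
                                           abs(m.offset + span / 2.0 - center),
                                           m.offset))
        if abs(best.offset + span / 2.0 - center) <= half:
            n_central += 1
    # valid start positions and how many put the match center inside the window
    starts = np.arange(0, L - span + 1)
    centers = starts + span / 2.0
    p0 = float(np.mean(np.abs(centers - center) <= half)) if len(starts) else 0.0
    if n_with == 0:
        return CentralityResult(pattern.name, len(windows), 0, 0, p0, None,
                                "no occurrences")
    p = float(stats.binomtest(n_central, n_with, p0, alternative="greater").pvalue)
    return CentralityResult(pattern.name, len(windows), n_with, n_central, p0, p, "ok")
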
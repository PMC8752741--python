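"""Condition-specific ChIP peak filtering and gene assignment.

The central operation removes tunicamycin (Tm) peaks that are also present
in the DMSO mock: a Tm peak whose bases are covered > 30% by mock peaks is
eliminated unless its pfloat (−log10 p, narrowPeak column 8) exceeds the
best-overlapping mock peak's by more than threefold, in which case it is
retained and flagged as rescued.  Replicate consistency is enforced by a
deterministic reciprocal-overlap filter, a documented stand-in for the IDR
model.  Surviving peaks are merged across timepoints and assigned to every
gene whose TSS lies within 1 kb of the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, ParameterError
from .io import PeakSet, empty_peak_frame


@dataclass(frozen=True)
class PeakFilterParams:
    overlap_frac: float = 0.30          # fraction of the Tm peak covered by mock peaks
    rescue_ratio: float = 3.0           # Tm pfloat / mock pfloat (−log10 scale)
    reproducibility_min_overlap: float = 0.5  # reciprocal overlap between replicates
    promoter_window: int = 1000         # bp from TSS for gene assignment

    def __post_init__(self):
        if not 0 < self.overlap_frac <= 1 or not 0 < self.reproducibility_min_overlap <= 1:
            raise ParameterError("overlap fractions must lie in (0, 1]")
        if self.rescue_ratio <= 1:
            raise ParameterError("rescue_ratio must be > 1")


def _overlap_len(s1, e1, s2, e2) -> int:
    return max(0, min(e1, e2) - max(s1, s2))


def reproducible_peaks(
    rep1: PeakSet, rep2: PeakSet, params: PeakFilterParams = PeakFilterParams()
) -> PeakSet:
    """Replicate-consistency filter (deterministic reciprocal-overlap stand-in).

    A rep1 peak is reproducible when some rep2 peak overlaps it by at least
    ``reproducibility_min_overlap`` of both peak lengths; the retained record
    (interval, summit, pfloat) comes from the higher-pfloat partner, so a
    merged record spanning sub-peaks keeps the summit of the strongest one.
    """
    for attr in ("tf", "condition", "timepoint"):
        if getattr(rep1, attr) != getattr(rep2, attr):
            raise ConsistencyError(f"replicates differ in {attr}")
    d1, d2 = rep1.peaks, rep2.peaks
    kept = []
    seen = set()
    for r1 in d1.itertuples(index=False):
        cand = d2[(d2["chrom"] == r1.chrom)]
        for r2 in cand.itertuples(index=False):
            ov = _overlap_len(r1.start, r1.end, r2.start, r2.end)
            if (ov >= params.reproducibility_min_overlap * (r1.end - r1.start)
                    and ov >= params.reproducibility_min_overlap * (r2.end - r2.start)):
                winner = r1 if r1.pfloat >= r2.pfloat else r2
                if winner.name not in seen:
                    seen.add(winner.name)
                    kept.append(winner)
                break
    df = pd.DataFrame(kept, columns=d1.columns) if kept else empty_peak_frame()
    out = rep1.with_peaks(df)
    out.replicate = None
    return out


def upr_specific_filter(
    tm: PeakSet, mock: PeakSet, params: PeakFilterParams = PeakFilterParams()
) -> tuple[PeakSet, PeakSet]:
    """Split Tm peaks into UPR-specific (retained) and mock-shared (eliminated).

    For each Tm peak, f = union of bases covered by overlapping mock peaks /
    Tm peak length.  f <= overlap_frac → retained; otherwise eliminated
    unless tm.pfloat / best-mock.pfloat > rescue_ratio (best = largest single
    overlap, ties to higher pfloat), in which case the peak is retained with
    ``rescued = True``.  A zero mock pfloat with overlap rescues (ratio +∞).
    The two outputs partition the input.
    """
    dt, dm = tm.peaks, mock.peaks
    retained_idx, eliminated_idx, rescued_flags = [], [], []
    for idx, r in zip(dt.index, dt.itertuples(index=False)):
        over = dm[(dm["chrom"] == r.chrom) & (dm["start"] < r.end) & (dm["end"] > r.start)]
        length = r.end - r.start
        if len(over):
            starts = np.maximum(over["start"].to_numpy(), r.start)
            ends = np.minimum(over["end"].to_numpy(), r.end)
            covered = _union_coverage(starts, ends)
            f = covered / length
        else:
            f = 0.0
        if f <= params.overlap_frac:
            retained_idx.append(idx)
            rescued_flags.append(False)
            continue
        ovlens = ends - starts
        best = over.assign(_ov=ovlens).sort_values(["_ov", "pfloat"], ascending=False).iloc[0]
        if best["pfloat"] == 0 or r.pfloat / best["pfloat"] > params.rescue_ratio:
            retained_idx.append(idx)
            rescued_flags.append(True)
        else:
            eliminated_idx.append(idx)
    ret = dt.loc[retained_idx].copy()
    ret["rescued"] = rescued_flags
    return tm.with_peaks(ret), tm.with_peaks(dt.loc[eliminated_idx].copy())


def _union_coverage(starts: np.ndarray, ends: np.ndarray) -> int:
    order = np.argsort(starts)
    covered, cur_s, cur_e = 0, None, None
    for s, e in zip(starts[order], ends[order]):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return int(covered)


def merge_across_timepoints(peaksets: list[PeakSet]) -> PeakSet:
    """Union of peak sets with >= 1 bp-overlap chains coalesced to their span.

    The merged record takes summit, pfloat and name from the member with the
    highest pfloat.  Output sorted by coordinate.
    """
    tfs = {ps.tf for ps in peaksets}
    if len(tfs) > 1:
        raise ConsistencyError(f"cannot merge peaks of different TFs: {tfs}")
    frames = [ps.peaks for ps in peaksets if len(ps)]
    if not frames:
        return PeakSet(empty_peak_frame(), tf=tfs.pop() if tfs else None, condition="Tm")
    allp = pd.concat(frames, ignore_index=True).sort_values(["chrom", "start", "end"])
    merged_rows = []
    cur = None
    for r in allp.itertuples(index=False):
        if cur is None or r.chrom != cur["chrom"] or r.start >= cur["end"]:
            if cur is not None:
                merged_rows.append(cur)
            cur = r._asdict()
        else:
            cur["end"] = max(cur["end"], r.end)
            if r.pfloat > cur["pfloat"]:
                for key in ("name", "score", "signal", "pfloat", "qvalue", "summit"):
                    cur[key] = getattr(r, key)
        cur["summit_offset"] = cur["summit"] - cur["start"]
    if cur is not None:
        merged_rows.append(cur)
    df = pd.DataFrame(merged_rows)
    df["summit_offset"] = df["summit"] - df["start"]
    return PeakSet(df.reset_index(drop=True), tf=next(iter(tfs)), condition="Tm")


def assign_peaks_to_genes(
    peaks: PeakSet,
    annotation: pd.DataFrame,
    params: PeakFilterParams = PeakFilterParams(),
) -> tuple[dict, dict, set, list]:
    """Assign peaks to genes whose TSS lies within ``promoter_window`` bp.

    Distance is strand-agnostic from the TSS to the peak interval (0 for
    overlap); the boundary is inclusive (distance == window assigns, 1 bp
    further does not).  Returns (peak→genes, gene→peaks, bound gene set,
    intergenic peak names).
    """
    peak2genes: dict[str, set] = {}
    gene2peaks: dict[str, set] = {}
    intergenic = []
    by_chrom = dict(tuple(annotation.groupby("chrom")))
    for r in peaks.peaks.itertuples(index=False):
        ann = by_chrom.get(r.chrom)
        if ann is None:
            intergenic.append(r.name)
            continue
        tss = ann["tss"].to_numpy()
        dist = np.maximum.reduce([r.start - tss, tss - r.end, np.zeros_like(tss)])
        hit = ann["gene_id"].to_numpy()[dist <= params.promoter_window]
        if len(hit):
            peak2genes[r.name] = set(hit)
            for g in hit:
                gene2peaks.setdefault(g, set()).add(r.name)
        else:
            intergenic.append(r.name)
    return peak2genes, gene2peaks, set(gene2peaks), intergenic


def classify_peak_location(
    peak_row, annotation: pd.DataFrame, promoter_window: int = 1000
) -> str:
    """Classify one peak by summit position relative to the nearest gene.

    Categories with precedence promoter > gene body > downstream > distal:
    promoter = within ``promoter_window`` bp upstream of a TSS (strand-aware),
    gene body = inside a gene interval, downstream = within the window beyond
    the gene 3' end, distal intergenic otherwise.
    """
    summit = peak_row.summit
    chrom = peak_row.chrom
    ann = annotation[annotation["chrom"] == chrom]
    categories = set()
    for g in ann.itertuples(index=False):
        if g.start <= summit < g.end:
            categories.add("gene body")
        if g.strand == "+":
            if g.start - promoter_window <= summit < g.start:
                categories.add("promoter")
            if g.end <= summit < g.end + promoter_window:
                categories.add("downstream")
        else:
            if g.end <= summit < g.end + promoter_window:
                categories.add("promoter")
            if g.start - promoter_window <= summit < g.start:
                categories.add("downstream")
    for cat in ("promoter", "gene body", "downstream"):
        if cat in categories:
            return cat
    return "distal intergenic"


def location_summary(peaks: PeakSet, annotation: pd.DataFrame,
                     promoter_window: int = 1000) -> pd.Series:
    cats = [classify_peak_location(r, annotation, promoter_window)
            for r in peaks.peaks.itertuples(index=False)]
    order = ["promoter", "gene body", "downstream", "distal intergenic"]
    return pd.Series(cats, dtype="object").value_counts().reindex(order, fill_value=0)
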
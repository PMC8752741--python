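"""Differential expression: normalization, per-contrast log2FC, and DEG calls.

Each contrast compares tunicamycin (Tm) against the mock (DMSO) control
within one genotype × timepoint.  Counts are normalized by median-of-ratios
size factors; the per-gene test is Welch's t on log2(normalized count +
pseudocount) — a documented stand-in for a negative-binomial GLM, chosen so
that the calling thresholds (|log2FC| > 1, BH-adjusted p < 0.01, total count
≥ 100 over the six samples of a contrast) can be applied exactly as stated.
All threshold inequalities are strict: a gene at log2FC = 1.0 exactly, or
padj = 0.01 exactly, is not a DEG; a contrast total count of 99 is untested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError, NormalizationError, ParameterError


@dataclass(frozen=True)
class DEGThresholds:
    """DEG calling thresholds (defaults are the study's printed values)."""

    lfc_min: float = 1.0       # |log2FC| must exceed this (strict)
    alpha: float = 0.01        # BH-adjusted p must be below this (strict)
    min_total_count: int = 100  # sum of raw counts over the 6 contrast samples
    pseudocount: float = 0.5

    def __post_init__(self):
        if self.lfc_min < 0 or not 0 < self.alpha < 1:
            raise ParameterError("lfc_min must be >= 0 and alpha in (0,1)")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_s = median over genes expressed in every sample of
    count_gs / geometric-mean_g.  Raises :class:`NormalizationError` when no
    gene is expressed in all samples (fall back to a pseudo-reference over
    genes nonzero in each sample if that happens on real data).
    """
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise NormalizationError(
            "no gene expressed in all samples; consider a pseudo-reference "
            "(median of ratios over genes nonzero in the sample)"
        )
    sub = mat[allpos]
    geo = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    factors = np.median(sub / geo, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _welch_log2(tm: np.ndarray, mock: np.ndarray) -> np.ndarray:
    """Vectorized Welch t-test p-values on rows; deterministic degenerate rules.

    Rows where both groups have zero variance: p = 1 when the means are equal,
    p = 0 when they differ (flagged upstream as degenerate fixtures).
    """
    n1, n2 = tm.shape[1], mock.shape[1]
    m1, m2 = tm.mean(axis=1), mock.mean(axis=1)
    v1 = tm.var(axis=1, ddof=1)
    v2 = mock.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    p = np.ones(tm.shape[0])
    ok = se2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1[ok] - m2[ok]) / np.sqrt(se2[ok])
        df = se2[ok] ** 2 / (
            (v1[ok] / n1) ** 2 / (n1 - 1) + (v2[ok] / n2) ** 2 / (n2 - 1)
        )
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    degen = ~ok & (m1 != m2)
    p[degen] = 0.0
    return p


def contrast_lfc(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    genotype: str,
    timepoint,
    thresholds: DEGThresholds = DEGThresholds(),
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """log2FC and Welch p for one genotype × timepoint contrast (Tm vs mock).

    Returns a per-gene frame with columns log2fc, p, padj, tested.  Genes
    whose raw counts over the six contrast samples total < min_total_count
    are untested (NaN p).  BH adjustment is within-contrast over tested genes.
    """
    sel = sheet[(sheet["genotype"] == genotype) & (sheet["timepoint"].astype(str) == str(timepoint))]
    tm_ids = sel[sel["treatment"] == "Tm"].sort_values("replicate")["sample_id"].tolist()
    mock_ids = sel[sel["treatment"] == "mock"].sort_values("replicate")["sample_id"].tolist()
    if not tm_ids or not mock_ids:
        raise DesignError(f"missing Tm or mock replicates for {genotype} at {timepoint}")
    if factors is None:
        factors = size_factors(counts)
    c = thresholds.pseudocount
    norm = counts / factors
    tm = norm[tm_ids].to_numpy(dtype=float)
    mock = norm[mock_ids].to_numpy(dtype=float)
    log2fc = np.log2((tm.mean(axis=1) + c) / (mock.mean(axis=1) + c))
    total = counts[tm_ids + mock_ids].sum(axis=1).to_numpy()
    tested = total >= thresholds.min_total_count
    p = np.full(len(counts), np.nan)
    p[tested] = _welch_log2(np.log2(tm + c)[tested], np.log2(mock + c)[tested])
    padj = np.full(len(counts), np.nan)
    if tested.any():
        padj[tested] = bh_adjust(p[tested])
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "padj": padj, "tested": tested},
        index=counts.index,
    )


def run_all_contrasts(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    thresholds: DEGThresholds = DEGThresholds(),
) -> pd.DataFrame:
    """All genotype × timepoint contrasts, stacked long with is_deg flags."""
    factors = size_factors(counts)
    frames = []
    for genotype in sheet["genotype"].unique():
        for timepoint in sheet.loc[sheet["genotype"] == genotype, "timepoint"].unique():
            res = contrast_lfc(counts, sheet, genotype, timepoint, thresholds, factors)
            res = res.reset_index().rename(columns={res.index.name or "index": "gene"})
            res.insert(1, "genotype", genotype)
            res.insert(2, "timepoint", timepoint)
            frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    out["is_deg"] = (
        out["tested"]
        & (out["log2fc"].abs() > thresholds.lfc_min)
        & (out["padj"] < thresholds.alpha)
    )
    return out


@dataclass
class DEGSet:
    """Per-contrast DEG gene sets plus their union across contrasts."""

    per_contrast: dict  # (genotype, timepoint) -> set of genes
    union: set

    @property
    def counts(self) -> dict:
        return {k: len(v) for k, v in self.per_contrast.items()}


def call_degs(results: pd.DataFrame, thresholds: DEGThresholds = DEGThresholds()) -> DEGSet:
    """Apply the strict DEG thresholds to a stacked contrast table."""
    is_deg = (
        results["tested"]
        & (results["log2fc"].abs() > thresholds.lfc_min)
        & (results["padj"] < thresholds.alpha)
    )
    per = {}
    for (genotype, timepoint), grp in results[is_deg].groupby(["genotype", "timepoint"], sort=False):
        per[(genotype, timepoint)] = set(grp["gene"])
    union = set().union(*per.values()) if per else set()
    return DEGSet(per_contrast=per, union=union)


def fisher_count_compare(n_deg_a: int, n_tested_a: int, n_deg_b: int, n_tested_b: int) -> float:
    """Two-sided Fisher exact p comparing DEG counts between two genotypes.

    Table rows are (DEG, tested − DEG) for genotype A and B; the universe of
    tested genes is made explicit by the caller.
    """
    cells = [n_deg_a, n_tested_a - n_deg_a, n_deg_b, n_tested_b - n_deg_b]
    if any(c < 0 for c in cells):
        raise ParameterError("negative cell in Fisher table")
    table = [[cells[0], cells[1]], [cells[2], cells[3]]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
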
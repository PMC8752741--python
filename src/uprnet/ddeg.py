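"""Differentially-differentially expressed genes (DDEGs).

A DDEG is a DEG whose Tm/DMSO log2 fold change differs significantly between
two genotypes at a timepoint.  The statistic is a pooled-variance two-sample
Student t on replicate-level log2 fold changes (Tm replicate i paired with
mock replicate i), two-sided, at raw p < 0.01 with no multiplicity
correction — matching the stated procedure.  Welch and BH variants are
available behind flags but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from statistics import median

import numpy as np
import pandas as pd
from scipy import stats

from .deg import bh_adjust, size_factors
from .exceptions import DesignError


def replicate_lfc(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    pseudocount: float = 0.5,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Replicate-level log2 fold changes, genes × (genotype, timepoint, replicate).

    rLFC_i = log2((ñ_Tm,i + c) / (ñ_mock,i + c)) on size-factor normalized
    counts, pairing Tm and mock replicates by replicate index.  Raises
    :class:`DesignError` when the replicate numbers differ (pairing undefined).
    """
    if factors is None:
        factors = size_factors(counts)
    norm = counts / factors
    cols = {}
    for (genotype, timepoint), grp in sheet.groupby(["genotype", "timepoint"], sort=False):
        tm = grp[grp["treatment"] == "Tm"].sort_values("replicate")
        mock = grp[grp["treatment"] == "mock"].sort_values("replicate")
        if len(tm) != len(mock):
            raise DesignError(
                f"{genotype} at {timepoint}: {len(tm)} Tm vs {len(mock)} mock replicates"
            )
        for (_, t_row), (_, m_row) in zip(tm.iterrows(), mock.iterrows()):
            ratio = (norm[t_row.sample_id] + pseudocount) / (norm[m_row.sample_id] + pseudocount)
            cols[(genotype, timepoint, int(t_row.replicate))] = np.log2(ratio)
    out = pd.DataFrame(cols, index=counts.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["genotype", "timepoint", "replicate"])
    return out


def ddeg_test(x, y, welch: bool = False) -> tuple[float, float]:
    """Two-sample t on two replicate-lfc vectors; returns (t, two-sided p).

    Pooled-variance Student by default.  Degenerate inputs: both vectors
    constant and equal -> (0, 1); both constant but unequal -> (±inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DesignError("each replicate vector needs length >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def ddeg_test_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled-variance Student t (genes × replicates arrays)."""
    n1, n2 = x.shape[1], y.shape[1]
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    diff = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), n1 + n2 - 2)
    zero = sp2 == 0
    t[zero] = np.where(diff[zero] == 0, 0.0, np.sign(diff[zero]) * np.inf)
    p[zero] = np.where(diff[zero] == 0, 1.0, 0.0)
    return t, p


@dataclass
class DDEGSet:
    """DDEG calls per genotype pair × timepoint, with per-pair unions."""

    records: pd.DataFrame               # gene, pair, timepoint, t, p, is_ddeg
    per_comparison: dict                # (pair, timepoint) -> set of genes
    per_pair_union: dict                # pair -> set (DDEG at >=1 timepoint)
    alpha: float = 0.01

    @property
    def comparison_counts(self) -> dict:
        return {k: len(v) for k, v in self.per_comparison.items()}

    @property
    def median_comparison_count(self) -> float:
        """Median DDEG count across pairwise comparisons (the control-set size)."""
        counts = list(self.comparison_counts.values())
        return float(median(counts)) if counts else 0.0


def call_ddegs(
    union_degs: set,
    rlfc: pd.DataFrame,
    genotype_pairs: list[tuple[str, str]] | None = None,
    timepoints: list | None = None,
    alpha: float = 0.01,
    welch: bool = False,
    bh: bool = False,
) -> DDEGSet:
    """Pairwise genotype comparisons of replicate log2FC, restricted to union DEGs.

    For each genotype pair and timepoint, every union-DEG gene is tested with
    the pooled-variance Student t; genes with p < alpha are DDEGs.  Per-pair
    unions collect genes significant at >= 1 timepoint.
    """
    genotypes = list(rlfc.columns.get_level_values("genotype").unique())
    if genotype_pairs is None:
        genotype_pairs = list(combinations(genotypes, 2))
    if timepoints is None:
        timepoints = list(rlfc.columns.get_level_values("timepoint").unique())
    genes = [g for g in rlfc.index if g in union_degs]
    sub = rlfc.loc[genes]
    rows = []
    per_comparison = {}
    for ga, gb in genotype_pairs:
        pair = f"{ga}_vs_{gb}"
        for tp in timepoints:
            x = sub[ga][tp].to_numpy(dtype=float)
            y = sub[gb][tp].to_numpy(dtype=float)
            if welch:
                t, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
            else:
                t, p = ddeg_test_matrix(x, y)
            if bh:
                p = bh_adjust(p)
            sig = p < alpha
            per_comparison[(pair, tp)] = {g for g, s in zip(genes, sig) if s}
            rows.append(pd.DataFrame({
                "gene": genes, "pair": pair, "timepoint": tp,
                "t": t, "p": p, "is_ddeg": sig,
            }))
    records = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["gene", "pair", "timepoint", "t", "p", "is_ddeg"])
    per_pair_union = {}
    for (pair, _), s in per_comparison.items():
        per_pair_union.setdefault(pair, set()).update(s)
    return DDEGSet(records=records, per_comparison=per_comparison,
                   per_pair_union=per_pair_union, alpha=alpha)
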
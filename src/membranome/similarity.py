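"""Tumor vs cell-line expression similarity over a gene subset.

All tumor samples of one tissue are correlated (Pearson, across genes) with
all cell lines of another tissue; each (tumor tissue, cell-line tissue) pair
yields a distribution of correlation coefficients.  Cognate pairs (same
tissue of origin) are compared against each non-cognate pair by Student's
t-test on the distribution means with a global Bonferroni correction over
all tests performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exprdata import ExpressionDataset

__all__ = [
    "CorrelationGroupSummary",
    "pairwise_correlations",
    "group_distributions",
    "tumor_cellline_summaries",
    "cognate_tests",
]


@dataclass
class CorrelationGroupSummary:
    tumor_tissue: str
    cellline_tissue: str
    correlations: np.ndarray
    five_number_summary: tuple[float, float, float, float, float]
    mean: float
    is_cognate: bool


def pairwise_correlations(
    ds: ExpressionDataset,
    gene_subset,
    group_a,
    group_b,
) -> pd.DataFrame:
    """Pearson r between every sample of group_a and every sample of group_b.

    Correlations run across the gene subset.  A zero-variance profile makes
    its pairs undefined; those entries are NaN with a warning.
    """
    genes = [g for g in gene_subset if g in ds.gene_ids]
    if len(genes) < 3:
        raise ValueError("need at least 3 genes in the subset")
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("sample groups must be disjoint")
    A = ds.values.loc[genes, group_a].to_numpy(dtype=float)
    B = ds.values.loc[genes, group_b].to_numpy(dtype=float)
    sd_a, sd_b = A.std(axis=0), B.std(axis=0)
    if (sd_a == 0).any() or (sd_b == 0).any():
        warnings.warn("zero-variance profiles: their correlations are undefined")
    Az = (A - A.mean(axis=0)) / np.where(sd_a == 0, np.nan, sd_a)
    Bz = (B - B.mean(axis=0)) / np.where(sd_b == 0, np.nan, sd_b)
    R = Az.T @ Bz / len(genes)
    return pd.DataFrame(R, index=group_a, columns=group_b)


def _five_number(values: np.ndarray) -> tuple[float, ...]:
    # linear-interpolation (type 7) quartiles; boxplot stats depend on this
    q = np.percentile(values, [0, 25, 50, 75, 100])
    return tuple(float(v) for v in q)


def group_distributions(
    corrs_by_pair: dict[tuple[str, str], np.ndarray]
) -> list[CorrelationGroupSummary]:
    """Summarize correlation distributions keyed by (tumor, cell-line) tissue."""
    summaries = []
    for (t_tissue, cl_tissue), values in sorted(corrs_by_pair.items()):
        values = np.asarray(values, dtype=float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            raise ValueError(f"empty correlation set for pair {(t_tissue, cl_tissue)}")
        summaries.append(
            CorrelationGroupSummary(
                tumor_tissue=t_tissue,
                cellline_tissue=cl_tissue,
                correlations=values,
                five_number_summary=_five_number(values),
                mean=float(values.mean()),
                is_cognate=t_tissue == cl_tissue,
            )
        )
    return summaries


def tumor_cellline_summaries(
    ds: ExpressionDataset, gene_subset
) -> list[CorrelationGroupSummary]:
    """All-pairs tumor x cell-line correlation summaries, by tissue pair."""
    tumors = ds.manifest[ds.manifest["sample_class"] == "tumor"]
    cls = ds.manifest[ds.manifest["sample_class"] == "cell_line"]
    corrs: dict[tuple[str, str], np.ndarray] = {}
    for t_tissue in sorted(tumors["tissue"].unique()):
        t_ids = list(tumors.index[tumors["tissue"] == t_tissue])
        for cl_tissue in sorted(cls["tissue"].unique()):
            cl_ids = list(cls.index[cls["tissue"] == cl_tissue])
            R = pairwise_correlations(ds, gene_subset, t_ids, cl_ids)
            corrs[(t_tissue, cl_tissue)] = R.to_numpy().ravel()
    return group_distributions(corrs)


def cognate_tests(summaries: list[CorrelationGroupSummary]) -> pd.DataFrame:
    """Cognate vs non-cognate mean-correlation tests, Bonferroni corrected.

    For each tumor tissue with a cognate cell line, the cognate correlation
    distribution is compared to each non-cognate one by a two-sample
    Student's t-test (Welch only when a variance degenerates, flagged).
    Adjusted p = raw p x (total tests), capped at 1.  The verdict column
    marks tumor tissues whose cognate mean is largest with every adjusted
    p < 0.01.
    """
    by_tumor: dict[str, list[CorrelationGroupSummary]] = {}
    for s in summaries:
        by_tumor.setdefault(s.tumor_tissue, []).append(s)
    rows = []
    for t_tissue, group in sorted(by_tumor.items()):
        cognate = [s for s in group if s.is_cognate]
        if not cognate:
            continue
        cog = cognate[0]
        for s in group:
            if s.is_cognate:
                continue
            if cog.correlations.size < 2 or s.correlations.size < 2:
                raise ValueError("need >= 2 correlations per distribution")
            degenerate = (
                cog.correlations.var() < 1e-15 or s.correlations.var() < 1e-15
            )
            t, p = stats.ttest_ind(
                cog.correlations, s.correlations, equal_var=not degenerate
            )
            if np.isnan(t):  # identical constant distributions
                t, p = 0.0, 1.0
            rows.append(
                {
                    "tumor_tissue": t_tissue,
                    "other_tissue": s.cellline_tissue,
                    "cognate_mean": cog.mean,
                    "other_mean": s.mean,
                    "t": float(t),
                    "p_raw": float(p),
                    "welch": degenerate,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    n_tests = len(df)
    df["p_bonferroni"] = np.minimum(df["p_raw"] * n_tests, 1.0)
    verdicts = []
    for t_tissue, sub in df.groupby("tumor_tissue"):
        ok = bool(
            (sub["p_bonferroni"] < 0.01).all()
            and (sub["cognate_mean"] > sub["other_mean"]).all()
        )
        verdicts.append((t_tissue, "cognate-max" if ok else "not-maximal"))
    verdict_map = dict(verdicts)
    df["verdict"] = df["tumor_tissue"].map(verdict_map)
    return df
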
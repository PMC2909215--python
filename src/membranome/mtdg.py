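"""Membranome tumor-deregulated genes (MTDG): directional consistency
between tumor-vs-normal and cell-line-vs-normal deregulation, plus the
cross-tissue overlap-significance matrix.

Consistency percentages use the tumor-side list as denominator:

    pct_up       = 100 * |t_up  ∩ cl_up |  / |t_up|
    pct_down     = 100 * |t_down ∩ cl_down| / |t_down|
    pct_combined = 100 * (|t_up ∩ cl_up| + |t_down ∩ cl_down|)
                       / (|t_up| + |t_down|)

Overlap significance is the one-sided hypergeometric tail
P(X >= observed overlap) with the analyzed gene universe as population,
computed in log space so that -log10 p survives p below 1e-300.  By default
the cross-tissue matrix counts only direction-consistent overlap
(up-with-up plus down-with-down); a direction-blind variant is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .sam import DeregulatedGeneLists

__all__ = [
    "MTDGTable",
    "ConsistencyReport",
    "OverlapMatrix",
    "identify_mtdg",
    "consistency_percentages",
    "overlap_significance",
    "overlap_matrix",
]


@dataclass
class MTDGTable:
    tissue: str
    cl_up: set[str]
    cl_down: set[str]
    t_up: set[str]
    t_down: set[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name in ("cl_up", "cl_down", "t_up", "t_down"):
            outside = getattr(self, name) - self.universe
            if outside:
                raise ValueError(
                    f"{name} gene outside universe: {sorted(outside)[:5]}"
                )
        if self.cl_up & self.cl_down:
            raise ValueError("cl_up and cl_down overlap")
        if self.t_up & self.t_down:
            raise ValueError("t_up and t_down overlap")


@dataclass
class ConsistencyReport:
    tissue: str
    counts: dict[str, int]  # the seven table rows
    pct_up: float
    pct_down: float
    pct_combined: float

    def rounded(self) -> dict[str, float]:
        from .catalog import round_half_away

        return {
            k: (round_half_away(v) if not math.isnan(v) else float("nan"))
            for k, v in {
                "pct_up": self.pct_up,
                "pct_down": self.pct_down,
                "pct_combined": self.pct_combined,
            }.items()
        }


@dataclass
class OverlapMatrix:
    neg_log10_p: pd.DataFrame  # rows: cell-line tissues; cols: tumor tissues
    diagonal_is_column_max: dict[str, bool]
    diagonal_is_row_max: dict[str, bool]


def identify_mtdg(
    tumor_lists: DeregulatedGeneLists,
    cl_lists: DeregulatedGeneLists,
    universe,
    tissue: str = "",
) -> MTDGTable:
    """Assemble the per-tissue MTDG table from the two comparisons."""
    if tumor_lists.fdr_target != cl_lists.fdr_target:
        raise ValueError("comparisons were run at different FDR targets")
    return MTDGTable(
        tissue=tissue,
        cl_up=set(cl_lists.up),
        cl_down=set(cl_lists.down),
        t_up=set(tumor_lists.up),
        t_down=set(tumor_lists.down),
        universe=frozenset(universe),
    )


def consistency_percentages(table: MTDGTable) -> ConsistencyReport:
    """Directional consistency of tumor deregulation in the cell lines."""
    inter_up = len(table.t_up & table.cl_up)
    inter_down = len(table.t_down & table.cl_down)
    n_t_up, n_t_down = len(table.t_up), len(table.t_down)
    counts = {
        "cl_up": len(table.cl_up),
        "cl_down": len(table.cl_down),
        "t_up": n_t_up,
        "t_down": n_t_down,
        "inter_up": inter_up,
        "inter_down": inter_down,
        "inter_combined": inter_up + inter_down,
    }
    pct_up = 100.0 * inter_up / n_t_up if n_t_up else float("nan")
    pct_down = 100.0 * inter_down / n_t_down if n_t_down else float("nan")
    denom = n_t_up + n_t_down
    pct_combined = 100.0 * (inter_up + inter_down) / denom if denom else float("nan")
    return ConsistencyReport(
        tissue=table.tissue,
        counts=counts,
        pct_up=pct_up,
        pct_down=pct_down,
        pct_combined=pct_combined,
    )


def _log_hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """log P(X >= k) for X ~ Hypergeom(N, K, n), exact, in log space."""
    kmax = min(K, n)
    if k <= max(0, K + n - N):
        return 0.0
    support = np.arange(k, kmax + 1)
    return float(logsumexp(hypergeom.logpmf(support, N, K, n)))


def overlap_significance(set_a, set_b, universe) -> tuple[float, float]:
    """One-sided overlap-enrichment p and -log10 p for two gene sets."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    if a - universe or b - universe:
        raise ValueError("sets must be subsets of the universe")
    logp = _log_hypergeom_tail(len(a & b), len(universe), len(a), len(b))
    logp = min(logp, 0.0)
    return math.exp(logp), -logp / math.log(10) + 0.0  # +0.0 avoids -0.0


def overlap_matrix(
    tables: list[MTDGTable], direction_aware: bool = True
) -> OverlapMatrix:
    """Cross-tissue -log10 overlap p-values between cell-line and tumor MTDG.

    Entry (cell-line tissue r, tumor tissue c) tests the overlap of r's
    deregulated set (cl_up ∪ cl_down) with c's (t_up ∪ t_down); with
    ``direction_aware`` the overlap count includes only genes whose
    direction agrees (up-with-up plus down-with-down).
    """
    if not tables:
        raise ValueError("no MTDG tables given")
    universe = tables[0].universe
    for t in tables[1:]:
        if t.universe != universe:
            raise ValueError("MTDG tables have mismatched universes")
    tissues = [t.tissue for t in tables]
    N = len(universe)
    mat = pd.DataFrame(index=tissues, columns=tissues, dtype=float)
    for row_t in tables:  # cell-line side
        a = row_t.cl_up | row_t.cl_down
        for col_t in tables:  # tumor side
            b = col_t.t_up | col_t.t_down
            if direction_aware:
                k = len(row_t.cl_up & col_t.t_up) + len(row_t.cl_down & col_t.t_down)
            else:
                k = len(a & b)
            logp = min(_log_hypergeom_tail(k, N, len(a), len(b)), 0.0)
            mat.loc[row_t.tissue, col_t.tissue] = -logp / math.log(10) + 0.0
    diag_col = {
        t: bool(mat.loc[t, t] >= mat[t].max()) for t in tissues
    }
    diag_row = {
        t: bool(mat.loc[t, t] >= mat.loc[t].max()) for t in tissues
    }
    return OverlapMatrix(
        neg_log10_p=mat,
        diagonal_is_column_max=diag_col,
        diagonal_is_row_max=diag_row,
    )
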
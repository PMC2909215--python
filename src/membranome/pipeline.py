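"""End-to-end drivers and truth-based recovery evaluation.

``mtdg_pipeline`` runs the differential-expression stage (permutation
engine at a fixed FDR target) for every tissue having tumor, cell-line and
normal samples, restricted to a gene universe (typically the catalog genes
on the platform), and assembles the per-tissue MTDG tables and consistency
reports.

``evaluate_recovery`` compares pipeline outputs against the generator's
truth table: estimated consistency percentages vs the planted retention
probabilities, classification-power ordering, cognate-correlation
maximality, overlap-matrix diagonal maximality, and sensitivity /
false-discovery proportion of the differential-expression stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exprdata import ExpressionDataset, quantile_normalize
from .mtdg import (
    ConsistencyReport,
    MTDGTable,
    OverlapMatrix,
    consistency_percentages,
    identify_mtdg,
    overlap_matrix,
)
from .sam import sam_permutation, select_significant
from .synth import TruthTable

__all__ = ["MtdgPipelineResult", "mtdg_pipeline", "evaluate_recovery"]


@dataclass
class MtdgPipelineResult:
    tables: dict[str, MTDGTable]
    reports: dict[str, ConsistencyReport]
    universe: frozenset[str]

    def pooled_percentages(self) -> dict[str, float]:
        """Aggregate consistency over tissues (summed numerators/denominators)."""
        num_up = sum(r.counts["inter_up"] for r in self.reports.values())
        num_down = sum(r.counts["inter_down"] for r in self.reports.values())
        den_up = sum(r.counts["t_up"] for r in self.reports.values())
        den_down = sum(r.counts["t_down"] for r in self.reports.values())
        return {
            "pct_up": 100.0 * num_up / den_up if den_up else float("nan"),
            "pct_down": 100.0 * num_down / den_down if den_down else float("nan"),
            "pct_combined": (
                100.0 * (num_up + num_down) / (den_up + den_down)
                if den_up + den_down
                else float("nan")
            ),
        }


def mtdg_pipeline(
    ds: ExpressionDataset,
    membranome_genes,
    fdr: float = 0.01,
    B: int = 300,
    seed: int = 0,
    normalize: bool = True,
) -> MtdgPipelineResult:
    """Identify MTDG per tissue at the given FDR target.

    Quantile normalization (rank-based, scale-agnostic) is applied first by
    default to absorb array-level study effects.  Only tissues with >= 2
    samples in each of the three classes are analyzed.
    """
    if normalize:
        work = quantile_normalize(ds) if "quantile" not in ds.stages else ds
    else:
        work = ds
    universe = frozenset(g for g in membranome_genes if g in ds.gene_ids)
    sub = work.subset_genes(sorted(universe))
    ss = np.random.SeedSequence(seed)
    tables: dict[str, MTDGTable] = {}
    reports: dict[str, ConsistencyReport] = {}
    tissues = sorted(sub.manifest["tissue"].unique())
    children = iter(ss.spawn(2 * len(tissues)))
    for tissue in tissues:
        groups = {
            cls: sub.samples_where(tissue=tissue, sample_class=cls)
            for cls in ("tumor", "cell_line", "normal")
        }
        seed_t = int(next(children).generate_state(1)[0] % (2**31 - 1))
        seed_cl = int(next(children).generate_state(1)[0] % (2**31 - 1))
        if any(len(v) < 2 for v in groups.values()):
            continue
        lists = {}
        for cls, seed_i in (("tumor", seed_t), ("cell_line", seed_cl)):
            ids = groups["normal"] + groups[cls]
            comp = sub.subset_samples(ids)
            # class labels sort as cell_line/tumor > normal, so d > 0 means
            # higher in the non-normal class
            labels = np.where(
                comp.manifest["sample_class"] == "normal", "a_normal", "b_case"
            )
            res = sam_permutation(comp, labels, B=B, seed=seed_i)
            lists[cls] = select_significant(
                res, fdr_target=fdr, comparison=f"{cls}_vs_normal/{tissue}"
            )
        tables[tissue] = identify_mtdg(
            lists["tumor"], lists["cell_line"], universe, tissue=tissue
        )
        reports[tissue] = consistency_percentages(tables[tissue])
    return MtdgPipelineResult(tables=tables, reports=reports, universe=universe)


@dataclass
class RecoveryReport:
    consistency: pd.DataFrame | None = None
    pooled: dict | None = None
    de_accuracy: pd.DataFrame | None = None
    cognate_max_fraction: float | None = None
    diagonal_max_fraction: float | None = None
    classification_ordering: pd.DataFrame | None = None


def evaluate_recovery(
    truth: TruthTable,
    mtdg_result: MtdgPipelineResult | None = None,
    summaries=None,
    overlap: OverlapMatrix | None = None,
    curve_comparison: pd.DataFrame | None = None,
) -> RecoveryReport:
    """Score pipeline outputs against the generative truth."""
    report = RecoveryReport()
    if mtdg_result is not None:
        missing = mtdg_result.universe - set(truth.genes.index)
        if missing:
            raise ValueError("pipeline universe contains genes unknown to truth")
        rows = []
        for tissue, table in mtdg_result.tables.items():
            rep = mtdg_result.reports[tissue]
            true_up = truth.planted_set(tissue, "up")
            true_down = truth.planted_set(tissue, "down")
            called_up, called_down = table.t_up, table.t_down
            tp = len(called_up & true_up) + len(called_down & true_down)
            n_called = len(called_up) + len(called_down)
            n_true = len(true_up) + len(true_down)
            rows.append(
                {
                    "tissue": tissue,
                    "pct_up": rep.pct_up,
                    "pct_down": rep.pct_down,
                    "sensitivity": tp / n_true if n_true else float("nan"),
                    "fdp": 1 - tp / n_called if n_called else float("nan"),
                }
            )
        report.consistency = pd.DataFrame(rows)
        report.de_accuracy = report.consistency[["tissue", "sensitivity", "fdp"]]
        report.pooled = mtdg_result.pooled_percentages()
    if summaries is not None:
        by_tumor: dict[str, list] = {}
        for s in summaries:
            by_tumor.setdefault(s.tumor_tissue, []).append(s)
        wins = 0
        total = 0
        for tissue, group in by_tumor.items():
            cognates = [s for s in group if s.is_cognate]
            if not cognates:
                continue
            total += 1
            best = max(group, key=lambda s: s.mean)
            wins += int(best.is_cognate)
        report.cognate_max_fraction = wins / total if total else float("nan")
    if overlap is not None:
        flags = list(overlap.diagonal_is_column_max.values())
        report.diagonal_max_fraction = sum(flags) / len(flags)
    if curve_comparison is not None:
        report.classification_ordering = curve_comparison
    return report
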
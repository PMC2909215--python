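"""Synthetic multi-study expression compendia with known ground truth.

The generator emulates the design of a multi-study tumor / cell-line /
normal-tissue microarray compendium on the log2 scale:

* a catalog ("membranome") fraction of genes (default 17%),
* per-tissue identity signatures present in every sample of that tissue,
  preferentially drawn from the membranome pool (concentration ``rho``),
* tumor deregulation (up and down gene blocks per tissue, membranome genes),
  retained in the cognate cell lines with probabilities ``retention_up`` <
  ``retention_down`` by default — the asymmetry the analysis is built to
  detect,
* a tumor-only admixture block mimicking infiltrating immune cells (absent
  from the clonal cell lines; drawn outside the membranome pool so the
  planted retention probabilities stay identifiable from the
  membranome-restricted analysis),
* per-study batch structure: an array-level shift per study plus a small
  gene-level residual (the shift is what quantile normalization removes;
  the residual is what it cannot),
* i.i.d. Gaussian noise.

Every draw flows from a single seed; regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exprdata import ExpressionDataset

__all__ = ["TissueDesign", "SynthConfig", "TruthTable", "generate_dataset"]


@dataclass(frozen=True)
class TissueDesign:
    n_cell_lines: int
    n_tumors: int
    n_normals: int


#: sample layout modeled on a published 8-tissue compendium: cell-line
#: counts as published, tumors clipped to 10-20 per tissue, normal samples
#: for the five tissues that have them
DEFAULT_TISSUES: dict[str, TissueDesign] = {
    "brain": TissueDesign(6, 20, 9),
    "breast": TissueDesign(6, 19, 0),
    "colon": TissueDesign(7, 20, 9),
    "kidney": TissueDesign(8, 11, 14),
    "leukemia": TissueDesign(6, 20, 0),
    "lung": TissueDesign(9, 20, 20),
    "melanoma": TissueDesign(8, 10, 0),
    "ovary": TissueDesign(6, 14, 7),
}


@dataclass
class SynthConfig:
    """Study-design parameters of the generator (log2-scale units)."""

    n_genes: int = 4000
    membranome_fraction: float = 0.17
    tissues: dict[str, TissueDesign] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES)
    )
    n_signature_genes: int = 40
    signature_membranome_concentration: float = 0.8  # rho
    signature_effect: float = 1.5  # beta, log2 units
    n_up: int = 25
    n_down: int = 25
    effect_up: float = 1.5  # delta_up
    effect_down: float = 1.5  # magnitude of delta_down
    retention_up: float = 0.5  # r_up
    retention_down: float = 0.8  # r_down
    til_block_size: int = 30
    til_effect: float = 1.0
    batch_sd: float = 0.3  # array-level per-study shift
    batch_gene_sd: float = 0.05  # per-gene per-study residual
    noise_sd: float = 0.4
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 42

    def validate(self) -> None:
        for name in ("retention_up", "retention_down",
                     "membranome_fraction", "signature_membranome_concentration"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        n_memb = int(round(self.n_genes * self.membranome_fraction))
        n_tis = len(self.tissues)
        sig_m = int(round(self.n_signature_genes
                          * self.signature_membranome_concentration))
        need_memb = n_tis * (sig_m + self.n_up + self.n_down)
        if need_memb > n_memb:
            raise ValueError(
                f"membranome pool too small: need {need_memb} of {n_memb}"
            )
        sig_o = self.n_signature_genes - sig_m
        need_other = n_tis * sig_o + self.til_block_size
        if need_other > self.n_genes - n_memb:
            raise ValueError("non-membranome pool too small for the design")


@dataclass
class TruthTable:
    """Ground-truth flags for a generated dataset.

    ``genes``: per-gene frame (membranome, til_block booleans).
    ``planted``: long frame (gene_id, tissue, role in {signature, up, down},
    retained_in_cellline) — retained is only meaningful for up/down roles.
    """

    genes: pd.DataFrame
    planted: pd.DataFrame

    def planted_set(self, tissue: str, role: str, retained=None) -> set[str]:
        sub = self.planted[
            (self.planted["tissue"] == tissue) & (self.planted["role"] == role)
        ]
        if retained is not None:
            sub = sub[sub["retained_in_cellline"] == retained]
        return set(sub["gene_id"])

    @property
    def membranome_genes(self) -> set[str]:
        return set(self.genes.index[self.genes["membranome"]])


def generate_dataset(
    config: SynthConfig, linear: bool = False
) -> tuple[ExpressionDataset, pd.DataFrame, TruthTable]:
    """Draw a compendium; returns (dataset, manifest, truth).

    ``linear=True`` exports 2**x values with scale_state 'linear' so the
    full preprocessing chain can be exercised; otherwise the dataset is on
    the log2 scale directly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(G)])

    n_memb = int(round(G * config.membranome_fraction))
    memb_idx = np.sort(rng.choice(G, size=n_memb, replace=False))
    memb_mask = np.zeros(G, dtype=bool)
    memb_mask[memb_idx] = True
    other_idx = np.nonzero(~memb_mask)[0]

    tissues = sorted(config.tissues)
    sig_m = int(round(config.n_signature_genes
                      * config.signature_membranome_concentration))
    sig_o = config.n_signature_genes - sig_m

    # disjoint allocation of planted structure
    memb_free = list(rng.permutation(memb_idx))
    other_free = list(rng.permutation(other_idx))

    def take(pool: list, k: int) -> np.ndarray:
        out = np.array([pool.pop() for _ in range(k)], dtype=int)
        return out

    signature: dict[str, np.ndarray] = {}
    planted_up: dict[str, np.ndarray] = {}
    planted_down: dict[str, np.ndarray] = {}
    retained_up: dict[str, np.ndarray] = {}
    retained_down: dict[str, np.ndarray] = {}
    for t in tissues:
        signature[t] = np.concatenate([take(memb_free, sig_m), take(other_free, sig_o)])
        planted_up[t] = take(memb_free, config.n_up)
        planted_down[t] = take(memb_free, config.n_down)
        retained_up[t] = rng.random(config.n_up) < config.retention_up
        retained_down[t] = rng.random(config.n_down) < config.retention_down
    til_idx = take(other_free, config.til_block_size)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=G)

    # sample layout and study assignment: one study for all cell lines,
    # one per tissue for tumors and for normals (multi-study structure)
    records = []
    for t in tissues:
        design = config.tissues[t]
        for k in range(design.n_cell_lines):
            records.append((f"{t}_cl_{k:02d}", t, "cell_line", "study_nci60"))
        for k in range(design.n_tumors):
            records.append((f"{t}_tumor_{k:02d}", t, "tumor", f"study_{t}_tumor"))
        for k in range(design.n_normals):
            records.append((f"{t}_normal_{k:02d}", t, "normal", f"study_{t}_normal"))
    manifest = pd.DataFrame(
        records, columns=["sample_id", "tissue", "sample_class", "study_id"]
    )
    manifest["replicate_group"] = ""

    studies = sorted(manifest["study_id"].unique())
    study_shift = {s: rng.normal(0.0, config.batch_sd) for s in studies}
    study_gene = {
        s: rng.normal(0.0, config.batch_gene_sd, size=G) for s in studies
    }

    n_samples = len(manifest)
    X = np.tile(baseline[:, None], (1, n_samples))
    for j, row in enumerate(manifest.itertuples(index=False)):
        t, cls, study = row.tissue, row.sample_class, row.study_id
        X[signature[t], j] += config.signature_effect
        if cls == "tumor":
            X[planted_up[t], j] += config.effect_up
            X[planted_down[t], j] -= config.effect_down
            X[til_idx, j] += config.til_effect
        elif cls == "cell_line":
            X[planted_up[t][retained_up[t]], j] += config.effect_up
            X[planted_down[t][retained_down[t]], j] -= config.effect_down
        X[:, j] += study_shift[study] + study_gene[study]
    X += rng.normal(0.0, config.noise_sd, size=X.shape)

    values = pd.DataFrame(X, index=gene_ids, columns=manifest["sample_id"])
    if linear:
        values = np.power(2.0, values)
        scale_state = "linear"
    else:
        scale_state = "log2"
    ds = ExpressionDataset(
        values=values, manifest=manifest, scale_state=scale_state
    )

    genes_df = pd.DataFrame(
        {"membranome": memb_mask, "til_block": np.isin(np.arange(G), til_idx)},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    planted_rows = []
    for t in tissues:
        for idx in signature[t]:
            planted_rows.append((gene_ids[idx], t, "signature", False))
        for idx, ret in zip(planted_up[t], retained_up[t]):
            planted_rows.append((gene_ids[idx], t, "up", bool(ret)))
        for idx, ret in zip(planted_down[t], retained_down[t]):
            planted_rows.append((gene_ids[idx], t, "down", bool(ret)))
    planted = pd.DataFrame(
        planted_rows, columns=["gene_id", "tissue", "role", "retained_in_cellline"]
    )
    truth = TruthTable(genes=genes_df, planted=planted)
    return ds, ds.manifest, truth
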
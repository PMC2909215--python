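"""Classification-power comparison of gene pools by resampling.

Equally sized gene lists are drawn at random from two pools (membrane-gene
catalog vs the rest of the transcriptome), a nearest-shrunken-centroid
classifier is cross-validated on each list, and misclassification rates are
averaged over many replicate draws, giving one misclassification-vs-size
curve per pool.  An exponential decay  rate ~ a*exp(-b*size) + c  is fitted
to each curve.

By default the gene lists have exactly the requested size and the classifier
runs unshrunken (Delta = 0): the list itself is the selection.  An optional
protocol instead uses the full pool and picks Delta per replicate to hit a
target active-gene count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.model_selection import StratifiedKFold

from .exprdata import ExpressionDataset
from .nsc import ShrunkenCentroidClassifier

__all__ = [
    "MisclassificationCurve",
    "ExponentialFit",
    "fit_nsc",
    "predict_nsc",
    "cv_misclassification",
    "power_curve",
    "fit_exponential",
]


@dataclass
class MisclassificationCurve:
    gene_pool_label: str
    sizes: list[int]
    mean_rates: np.ndarray  # one per size
    n_replicates: int
    per_replicate_rates: np.ndarray  # sizes x replicates
    fit: "ExponentialFit | None" = None


@dataclass
class ExponentialFit:
    a: float
    b: float
    c: float
    fitted: np.ndarray
    residuals: np.ndarray
    converged: bool


def _labels_from(ds: ExpressionDataset, labels) -> np.ndarray:
    if labels is None:
        return ds.manifest["tissue"].to_numpy()
    labels = np.asarray(labels)
    if labels.shape[0] != ds.n_samples:
        raise ValueError("one label per sample required")
    return labels


def fit_nsc(
    ds: ExpressionDataset,
    labels=None,
    shrinkage: float = 0.0,
    priors="proportional",
) -> ShrunkenCentroidClassifier:
    """Fit the shrunken-centroid model on a dataset (log2 scale expected)."""
    if ds.scale_state != "log2":
        raise ValueError("classification expects log2-scale data")
    model = ShrunkenCentroidClassifier(shrinkage=shrinkage, priors=priors)
    model.fit(ds.values.to_numpy().T, _labels_from(ds, labels))
    model.gene_ids_ = list(ds.gene_ids)
    return model


def predict_nsc(model: ShrunkenCentroidClassifier, profiles: pd.DataFrame):
    """Predict labels for genes x samples profiles aligned by gene id.

    Every gene active in the model must be present in the profiles.
    """
    genes = getattr(model, "gene_ids_", None)
    if genes is None:
        raise ValueError("model was not fitted through fit_nsc")
    missing = [
        g for g, act in zip(genes, model.active_mask_) if act and g not in profiles.index
    ]
    if missing:
        raise ValueError(f"profiles are missing active genes: {missing[:5]} ...")
    # inactive genes absent from the profiles contribute nothing; fill with
    # the overall centroid so the matrix aligns
    X = np.empty((profiles.shape[1], len(genes)))
    for j, g in enumerate(genes):
        if g in profiles.index:
            X[:, j] = profiles.loc[g].to_numpy()
        else:
            X[:, j] = model.overall_centroid_[j]
    return model.predict(X), model.decision_function(X)


def cv_misclassification(
    ds: ExpressionDataset,
    labels=None,
    shrinkage: float = 0.0,
    n_folds: int = 5,
    seed: int | None = None,
) -> float:
    """Stratified k-fold cross-validated misclassification rate in [0, 1].

    Folds are shuffled from ``seed``; samples are processed in sample_id
    order so the estimate does not depend on column order.
    """
    y = _labels_from(ds, labels)
    order = np.argsort(ds.manifest.index.to_numpy())
    X = ds.values.to_numpy().T[order]
    y = np.asarray(y)[order]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs at least 2 classes")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    folds = int(min(n_folds, counts.min()))
    if folds < n_folds:
        warnings.warn(
            f"reducing folds from {n_folds} to {folds}: smallest class has "
            f"{counts.min()} samples"
        )
    if folds < 2:
        raise ValueError("smallest class too small for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = 0
    for train, test in skf.split(X, y):
        model = ShrunkenCentroidClassifier(shrinkage=shrinkage)
        model.fit(X[train], y[train])
        errors += int((model.predict(X[test]) != y[test]).sum())
    return errors / len(y)


def power_curve(
    ds: ExpressionDataset,
    labels=None,
    membranome_pool=(),
    other_pool=(),
    sizes=(5, 10, 25, 50, 100),
    n_replicates: int = 1000,
    n_folds: int = 5,
    shrinkage: float = 0.0,
    seed: int = 0,
) -> tuple[MisclassificationCurve, MisclassificationCurve]:
    """Resampled misclassification curves for two gene pools.

    For each size N and each replicate, N genes are drawn uniformly without
    replacement from each pool and cross-validated; per-replicate rates are
    retained for paired comparison.  Deterministic given ``seed``; pools are
    sorted first so results do not depend on input gene order.
    """
    pools = {
        "membranome": sorted(membranome_pool),
        "not_membranome": sorted(other_pool),
    }
    sizes = [int(s) for s in sizes]
    for name, pool in pools.items():
        missing = set(pool) - set(ds.gene_ids)
        if missing:
            raise ValueError(f"{name} pool genes absent from dataset: {sorted(missing)[:5]}")
        if max(sizes) > len(pool):
            raise ValueError(f"size {max(sizes)} exceeds {name} pool ({len(pool)})")

    y = _labels_from(ds, labels)
    rates = {
        name: np.empty((len(sizes), n_replicates)) for name in pools
    }
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        for si, size in enumerate(sizes):
            for name, pool in pools.items():
                genes = rng.choice(pool, size=size, replace=False)
                sub = ds.subset_genes(genes)
                fold_seed = int(rng.integers(2**31 - 1))
                rates[name][si, r] = cv_misclassification(
                    sub, y, shrinkage=shrinkage, n_folds=n_folds, seed=fold_seed
                )
    curves = tuple(
        MisclassificationCurve(
            gene_pool_label=name,
            sizes=sizes,
            mean_rates=rates[name].mean(axis=1),
            n_replicates=n_replicates,
            per_replicate_rates=rates[name],
        )
        for name in ("membranome", "not_membranome")
    )
    return curves


def choose_shrinkage_for_size(
    ds: ExpressionDataset, labels=None, target_size: int = 10, tol: int = 0
) -> float:
    """Bisect the shrinkage Delta so the active-gene count hits a target.

    Supports the alternative resampling protocol in which the full gene
    pool is used and the classifier size is controlled through Delta rather
    than through explicit gene lists.  Returns the smallest Delta found
    whose active set is within ``tol`` genes of ``target_size`` (the count
    is a step function of Delta, so an exact hit may not exist; the closest
    achievable count from above is used).
    """
    y = _labels_from(ds, labels)
    X = ds.values.to_numpy().T
    base = ShrunkenCentroidClassifier(shrinkage=0.0).fit(X, y)
    if target_size >= ds.n_genes:
        return 0.0
    lo, hi = 0.0, float(np.abs(base.offsets_).max())
    for _ in range(60):
        mid = (lo + hi) / 2
        n_active = ShrunkenCentroidClassifier(shrinkage=mid).fit(X, y).n_active_genes_
        if n_active > target_size:
            lo = mid
        elif n_active < target_size:
            hi = mid
        else:
            return mid
    n_lo = ShrunkenCentroidClassifier(shrinkage=lo).fit(X, y).n_active_genes_
    if abs(n_lo - target_size) > tol:
        warnings.warn(
            f"no Delta gives exactly {target_size} active genes; "
            f"closest achievable count is {n_lo}"
        )
    return lo


def fit_exponential(curve_or_sizes, rates=None) -> ExponentialFit:
    """Least-squares fit of rate = a*exp(-b*size) + c with b >= 0, c in [0,1].

    Initialization: c from the minimum rate, a from the range, b from a
    log-linear regression on (rate - c).  Non-convergence is reported with a
    flag and the best iterate is returned.
    """
    if isinstance(curve_or_sizes, MisclassificationCurve):
        sizes = np.asarray(curve_or_sizes.sizes, dtype=float)
        y = np.asarray(curve_or_sizes.mean_rates, dtype=float)
    else:
        sizes = np.asarray(curve_or_sizes, dtype=float)
        y = np.asarray(rates, dtype=float)
    if sizes.size < 4:
        raise ValueError("need at least 4 points for the exponential fit")

    c0 = float(y.min())
    a0 = float(max(y.max() - y.min(), 1e-6))
    resid0 = np.clip(y - c0, 1e-9, None)
    slope = np.polyfit(sizes, np.log(resid0), 1)[0]
    b0 = float(np.clip(-slope, 1e-6, 10.0))

    def model(params, x):
        a, b, c = params
        return a * np.exp(-b * x) + c

    res = optimize.least_squares(
        lambda p: model(p, sizes) - y,
        x0=[a0, b0, min(max(c0, 0.0), 1.0)],
        bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, 1.0]),
        method="trf",
        max_nfev=5000,
    )
    fitted = model(res.x, sizes)
    converged = bool(res.success)
    if not converged:
        warnings.warn("exponential fit did not converge; returning best iterate")
    return ExponentialFit(
        a=float(res.x[0]),
        b=float(res.x[1]),
        c=float(res.x[2]),
        fitted=fitted,
        residuals=y - fitted,
        converged=converged,
    )


def paired_pool_comparison(
    curve_a: MisclassificationCurve, curve_b: MisclassificationCurve
) -> pd.DataFrame:
    """Per-size paired one-sided test that pool A misclassifies less than B."""
    if curve_a.sizes != curve_b.sizes:
        raise ValueError("curves were computed on different size grids")
    rows = []
    for i, size in enumerate(curve_a.sizes):
        diff = curve_a.per_replicate_rates[i] - curve_b.per_replicate_rates[i]
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(
                curve_a.per_replicate_rates[i],
                curve_b.per_replicate_rates[i],
                alternative="less",
            )
        rows.append(
            {
                "size": size,
                "mean_a": curve_a.mean_rates[i],
                "mean_b": curve_b.mean_rates[i],
                "mean_diff": float(diff.mean()),
                "t": float(t),
                "p_one_sided": float(p),
            }
        )
    return pd.DataFrame(rows)
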
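"""Expression matrices, sample manifests and the array preprocessing chain.

The preprocessing chain mirrors standard single-channel array practice:
technical-replicate averaging, per-array scaling to a trimmed mean target
(default 500), quantile normalization across arrays, and a floored log2
transform.  Stage order is fixed (average -> scale -> quantile -> log2) and
enforced; each :class:`ExpressionDataset` tracks which stages have run.

The numeric workhorses are sklearn-style transformers operating on
samples x genes arrays (:class:`TrimmedMeanScaler`, :class:`QuantileNormalizer`,
:class:`Log2Floor`); the dataset-level functions are thin wrappers that add
manifest bookkeeping and the stage guard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "ExpressionDataset",
    "TrimmedMeanScaler",
    "QuantileNormalizer",
    "Log2Floor",
    "average_replicates",
    "scale_to_trimmed_mean",
    "quantile_normalize",
    "log2_transform",
    "preprocess",
    "read_matrix",
    "read_manifest",
    "validate_manifest",
]

MANIFEST_COLUMNS = ("sample_id", "tissue", "sample_class", "study_id")
SAMPLE_CLASSES = ("tumor", "cell_line", "normal")


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check and normalize a sample manifest (sample_id becomes the index)."""
    df = manifest.copy()
    if df.index.name != "sample_id":
        if "sample_id" not in df.columns:
            raise ValueError("manifest needs a sample_id column")
        df = df.set_index("sample_id")
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample_id in manifest: {dup}")
    for col in ("tissue", "sample_class"):
        if col not in df.columns or df[col].isna().any() or (df[col] == "").any():
            raise ValueError(f"manifest column {col!r} must be present and complete")
    bad = set(df["sample_class"]) - set(SAMPLE_CLASSES)
    if bad:
        raise ValueError(f"unknown sample_class values: {sorted(bad)}")
    if "study_id" not in df.columns:
        df["study_id"] = "study0"
    if "replicate_group" not in df.columns:
        df["replicate_group"] = ""
    df["replicate_group"] = df["replicate_group"].fillna("")
    return df


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix bound to a sample manifest.

    ``scale_state`` is 'linear' or 'log2'; ``stages`` records preprocessing
    stages already applied, used to refuse out-of-order runs.
    """

    values: pd.DataFrame  # genes x samples
    manifest: pd.DataFrame  # indexed by sample_id
    scale_state: str = "linear"
    stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.manifest = validate_manifest(self.manifest)
        if list(self.values.columns) != list(self.manifest.index):
            if set(self.values.columns) != set(self.manifest.index):
                raise ValueError("matrix columns and manifest sample_ids differ")
            self.values = self.values[self.manifest.index]
        if not self.values.index.is_unique:
            raise ValueError("duplicate gene ids in matrix")
        if self.values.isna().any().any():
            raise ValueError("matrix contains missing values")
        if self.scale_state not in ("linear", "log2"):
            raise ValueError(f"bad scale_state {self.scale_state!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionDataset":
        genes = [g for g in genes if g in self.values.index]
        return replace(self, values=self.values.loc[genes], manifest=self.manifest)

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        sample_ids = list(sample_ids)
        return replace(
            self,
            values=self.values[sample_ids],
            manifest=self.manifest.loc[sample_ids],
        )

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids matching manifest equality conditions, e.g. tissue='brain'."""
        mask = pd.Series(True, index=self.manifest.index)
        for col, val in conditions.items():
            mask &= self.manifest[col] == val
        return list(self.manifest.index[mask])


# ---------------------------------------------------------------------------
# sklearn-style transformers (rows = samples, columns = genes)


class TrimmedMeanScaler(TransformerMixin, BaseEstimator):
    """Scale each sample so its trimmed mean equals ``target``.

    The trimmed mean discards the top and bottom ``trim_fraction`` of values
    (``scipy.stats.trim_mean`` convention: floor(n * fraction) from each end).
    Stateless: ``fit`` only validates.
    """

    def __init__(self, target: float = 500.0, trim_fraction: float = 0.02):
        self.target = target
        self.trim_fraction = trim_fraction

    def fit(self, X, y=None):
        X = check_array(X)
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        tm = np.apply_along_axis(stats.trim_mean, 1, X, self.trim_fraction)
        if np.any(tm <= 0):
            raise ValueError("trimmed mean <= 0 for at least one sample")
        return X * (self.target / tm)[:, None]


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Force every sample to share the same value distribution.

    ``fit`` stores the reference distribution (across-sample mean of order
    statistics); ``transform`` maps each sample's values onto it by rank.
    Tied values receive the mean of the reference values at the tied
    positions (mid-rank dialect), which keeps the map deterministic and the
    operation idempotent on tie-free data.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != self.reference_.size:
            raise ValueError("feature count differs from the fitted reference")
        out = np.empty_like(X, dtype=float)
        ref_cumsum = np.concatenate([[0.0], np.cumsum(self.reference_)])
        for i, row in enumerate(X):
            uniq, inverse, counts = np.unique(
                row, return_inverse=True, return_counts=True
            )
            starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
            block_means = (
                ref_cumsum[starts + counts] - ref_cumsum[starts]
            ) / counts
            out[i] = block_means[inverse]
        return out


class Log2Floor(TransformerMixin, BaseEstimator):
    """log2(max(x, floor)); floor must be positive."""

    def __init__(self, floor: float = 1.0):
        self.floor = floor

    def fit(self, X, y=None):
        if self.floor <= 0:
            raise ValueError("floor must be > 0")
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return np.log2(np.maximum(X, self.floor))


# ---------------------------------------------------------------------------
# dataset-level operations with stage guard


def _guard(ds: ExpressionDataset, stage: str, forbidden_after: tuple[str, ...]):
    done = set(ds.stages)
    late = done & set(forbidden_after)
    if late:
        raise ValueError(
            f"stage {stage!r} must run before {sorted(late)} (fixed chain: "
            "average -> scale -> quantile -> log2)"
        )


def average_replicates(ds: ExpressionDataset) -> ExpressionDataset:
    """Collapse technical-replicate groups to their per-gene arithmetic mean.

    A replicate group spanning different tissues or sample classes is an
    error; samples without a replicate_group pass through untouched.
    """
    _guard(ds, "average", ("scale", "quantile", "log2"))
    groups = ds.manifest["replicate_group"]
    keep_cols: list[str] = []
    new_cols: dict[str, np.ndarray] = {}
    new_rows: list[pd.Series] = []
    for gid, sub in ds.manifest[groups != ""].groupby("replicate_group", sort=True):
        if sub["tissue"].nunique() > 1 or sub["sample_class"].nunique() > 1:
            raise ValueError(
                f"replicate group {gid!r} spans different tissues/classes"
            )
        rep_ids = list(sub.index)
        new_cols[rep_ids[0]] = ds.values[rep_ids].mean(axis=1).to_numpy()
        row = sub.iloc[0].copy()
        row["replicate_group"] = ""
        row.name = rep_ids[0]
        new_rows.append(row)
    keep_cols = list(ds.manifest.index[groups == ""])
    values = ds.values[keep_cols].copy()
    manifest = ds.manifest.loc[keep_cols].copy()
    for rid in sorted(new_cols):
        values[rid] = new_cols[rid]
    if new_rows:
        manifest = pd.concat([manifest, pd.DataFrame(new_rows).sort_index()])
    manifest = manifest.loc[list(values.columns)]
    return ExpressionDataset(
        values=values,
        manifest=manifest.reset_index().rename(columns={"index": "sample_id"}),
        scale_state=ds.scale_state,
        stages=ds.stages + ("average",),
    )


def scale_to_trimmed_mean(
    ds: ExpressionDataset, target: float = 500.0, trim_fraction: float = 0.02
) -> ExpressionDataset:
    """Scale every sample column to a trimmed mean of ``target``."""
    if ds.scale_state != "linear":
        raise ValueError("trimmed-mean scaling requires linear-scale data")
    _guard(ds, "scale", ("quantile", "log2"))
    if (ds.values.to_numpy() < 0).any():
        raise ValueError("negative values on the linear scale")
    scaler = TrimmedMeanScaler(target=target, trim_fraction=trim_fraction)
    X = scaler.fit_transform(ds.values.to_numpy().T).T
    # definitional postcondition: the trimmed mean of every column is target
    tm = np.apply_along_axis(stats.trim_mean, 0, X, trim_fraction)
    assert np.allclose(tm, target, rtol=1e-9)
    return replace(
        ds,
        values=pd.DataFrame(X, index=ds.values.index, columns=ds.values.columns),
        stages=ds.stages + ("scale",),
    )


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Quantile-normalize samples jointly across the loaded dataset."""
    _guard(ds, "quantile", ("log2",))
    if ds.n_samples < 2:
        warnings.warn("single-sample dataset: quantile normalization is a no-op")
        return replace(ds, stages=ds.stages + ("quantile",))
    qn = QuantileNormalizer()
    X = qn.fit_transform(ds.values.to_numpy().T).T
    return replace(
        ds,
        values=pd.DataFrame(X, index=ds.values.index, columns=ds.values.columns),
        stages=ds.stages + ("quantile",),
    )


def log2_transform(ds: ExpressionDataset, floor: float = 1.0) -> ExpressionDataset:
    """Floored log2 transform; flips scale_state to 'log2'."""
    if ds.scale_state != "linear":
        raise ValueError("data is already on the log2 scale")
    tr = Log2Floor(floor=floor)
    X = tr.fit_transform(ds.values.to_numpy().T).T
    return replace(
        ds,
        values=pd.DataFrame(X, index=ds.values.index, columns=ds.values.columns),
        scale_state="log2",
        stages=ds.stages + ("log2",),
    )


def preprocess(
    ds: ExpressionDataset,
    target: float = 500.0,
    trim_fraction: float = 0.02,
    floor: float = 1.0,
) -> ExpressionDataset:
    """The full fixed chain: average -> scale -> quantile -> log2."""
    return log2_transform(
        quantile_normalize(
            scale_to_trimmed_mean(
                average_replicates(ds), target=target, trim_fraction=trim_fraction
            )
        ),
        floor=floor,
    )


# ---------------------------------------------------------------------------
# I/O


def read_matrix(path) -> pd.DataFrame:
    """TSV expression matrix: first column gene_id, header sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_manifest(path) -> pd.DataFrame:
    return validate_manifest(pd.read_csv(path, sep="\t", dtype=str))


def load_dataset(matrix_path, manifest_path, scale_state="linear") -> ExpressionDataset:
    return ExpressionDataset(
        values=read_matrix(matrix_path),
        manifest=read_manifest(manifest_path),
        scale_state=scale_state,
    )
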
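import numpy as np
import pandas as pd
import pytest

from membranome.catalog import CatalogRules, GeneAnnotationRecord
from membranome.exprdata import ExpressionDataset


def make_dataset(
    values,
    gene_ids=None,
    tissues=None,
    sample_classes=None,
    studies=None,
    replicate_groups=None,
    scale_state="linear",
):
    """Build a small ExpressionDataset from a 2-D array (genes x samples)."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    manifest = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue": tissues or ["t"] * n_samples,
            "sample_class": sample_classes or ["tumor"] * n_samples,
            "study_id": studies or ["study0"] * n_samples,
            "replicate_group": replicate_groups or [""] * n_samples,
        }
    )
    return ExpressionDataset(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        manifest=manifest,
        scale_state=scale_state,
    )


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def simple_rules():
    return CatalogRules(
        plasma_membrane_terms=frozenset({"plasma_membrane", "cell_surface"}),
        intracellular_terms=frozenset({"nucleus", "mitochondrion", "cytosol"}),
        include_overrides=frozenset({"GPI1"}),
        exclude_overrides=frozenset({"FAKE1"}),
    )


@pytest.fixture
def twenty_gene_annotations():
    """5 compartment-matched, 1 include-override (GPI-anchored, no other
    evidence), 1 TM-domain gene with only intracellular terms, 13 blanks."""
    records = []
    for i in range(5):
        records.append(
            GeneAnnotationRecord(
                gene_id=f"PM{i}",
                compartment_terms=frozenset({"plasma_membrane"}),
                has_tm_domain=(i % 2 == 0),
                functional_category="receptor",
                on_array=(i < 3),
            )
        )
    records.append(GeneAnnotationRecord(gene_id="GPI1", functional_category="anchor"))
    records.append(
        GeneAnnotationRecord(
            gene_id="MITO1",
            compartment_terms=frozenset({"mitochondrion"}),
            has_tm_domain=True,
        )
    )
    for i in range(13):
        records.append(GeneAnnotationRecord(gene_id=f"BLANK{i}"))
    return records
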
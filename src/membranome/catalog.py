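"""Membrane-protein gene catalog ("Membranome") construction.

A gene is admitted to the catalog from three evidence channels: subcellular
compartment annotation (accept-list of plasma-membrane terms, reject-list of
intracellular terms), predicted transmembrane topology, and manual override
lists correcting false positives/negatives of the automatic rules (e.g.
GPI-anchored proteins that carry neither a TM segment nor a useful
compartment term).  Membership logic::

    member  <=>  override_include
              or (plasma-membrane term present       and not override_exclude)
              or (TM domain and no intracellular term and not override_exclude)

A signal peptide alone never suffices (it would sweep in secreted proteins).
Term accept/reject lists are plain configuration, not hard-coded ontology
identifiers, because ontology versions drift.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

__all__ = [
    "GeneAnnotationRecord",
    "CatalogRules",
    "MembranomeCatalog",
    "CoverageReport",
    "classify_gene",
    "build_catalog",
    "array_coverage",
    "category_representation",
    "read_annotations",
    "write_catalog",
]

#: reason codes emitted by :func:`classify_gene`
REASONS = (
    "override_include",
    "override_exclude",
    "compartment_match",
    "tm_evidence",
    "no_evidence",
    "intracellular_reject",
)


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (display convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class GeneAnnotationRecord:
    """Per-gene evidence used to decide catalog membership."""

    gene_id: str
    compartment_terms: frozenset[str] = frozenset()
    has_tm_domain: bool = False
    has_signal_peptide: bool = False
    functional_category: str = "unclassified"
    on_array: bool = False


@dataclass(frozen=True)
class CatalogRules:
    """Accept/reject term lists plus manual override gene lists."""

    plasma_membrane_terms: frozenset[str] = frozenset()
    intracellular_terms: frozenset[str] = frozenset()
    include_overrides: frozenset[str] = frozenset()
    exclude_overrides: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        clash = self.include_overrides & self.exclude_overrides
        if clash:
            raise ValueError(
                f"genes in both include and exclude overrides: {sorted(clash)}"
            )


@dataclass
class MembranomeCatalog:
    """Result of :func:`build_catalog`."""

    members: set[str]
    evidence: dict[str, str]  # gene_id -> reason code (members and non-members)
    n_total_genes: int
    n_on_array: int

    @property
    def membership_fraction(self) -> float:
        return len(self.members) / self.n_total_genes


@dataclass
class CoverageReport:
    n_members: int
    n_on_array: int
    percentage: float
    percentage_rounded: int


def classify_gene(
    record: GeneAnnotationRecord, rules: CatalogRules
) -> tuple[bool, str]:
    """Decide catalog membership for one gene.

    Returns ``(member, reason)`` with reason one of :data:`REASONS`.
    Override lists take precedence over automatic evidence; deterministic.
    """
    if record.gene_id in rules.include_overrides:
        return True, "override_include"
    if record.gene_id in rules.exclude_overrides:
        return False, "override_exclude"
    if record.compartment_terms & rules.plasma_membrane_terms:
        return True, "compartment_match"
    if record.compartment_terms & rules.intracellular_terms:
        return False, "intracellular_reject"
    if record.has_tm_domain:
        return True, "tm_evidence"
    return False, "no_evidence"


def build_catalog(
    annotations: Iterable[GeneAnnotationRecord], rules: CatalogRules
) -> MembranomeCatalog:
    """Classify every gene and assemble the catalog.

    Raises on duplicate gene ids; override ids absent from the annotation
    table only raise a warning (stale manual lists are common).
    """
    records = list(annotations)
    if not records:
        raise ValueError("annotation table is empty")
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id in annotations: {rec.gene_id!r}")
        seen.add(rec.gene_id)

    unknown = (rules.include_overrides | rules.exclude_overrides) - seen
    if unknown:
        warnings.warn(
            f"override gene ids not present in annotations: {sorted(unknown)}",
            stacklevel=2,
        )

    members: set[str] = set()
    evidence: dict[str, str] = {}
    n_on_array = 0
    for rec in records:
        is_member, reason = classify_gene(rec, rules)
        evidence[rec.gene_id] = reason
        if is_member:
            members.add(rec.gene_id)
            if rec.on_array:
                n_on_array += 1
    return MembranomeCatalog(
        members=members,
        evidence=evidence,
        n_total_genes=len(records),
        n_on_array=n_on_array,
    )


def array_coverage(
    catalog: MembranomeCatalog, array_genes: Iterable[str]
) -> CoverageReport:
    """Fraction of catalog members represented on an expression platform."""
    if not catalog.members:
        raise ValueError("catalog has no members")
    on_array = catalog.members & set(array_genes)
    pct = 100.0 * len(on_array) / len(catalog.members)
    return CoverageReport(
        n_members=len(catalog.members),
        n_on_array=len(on_array),
        percentage=pct,
        percentage_rounded=round_half_away(pct),
    )


def category_representation(
    catalog: MembranomeCatalog,
    annotations: Iterable[GeneAnnotationRecord],
) -> pd.DataFrame:
    """Functional-category composition of the catalog vs its on-array subset.

    For each category present in the catalog, tests the 2x2 table
    (category / not-category) x (on-array / off-array), restricted to catalog
    members, with a two-sided exact test (hypergeometric enumeration via
    Fisher's exact test).  Categories absent from the catalog are omitted.
    """
    by_gene = {rec.gene_id: rec for rec in annotations}
    member_recs = [by_gene[g] for g in sorted(catalog.members)]
    n_members = len(member_recs)
    n_array = sum(r.on_array for r in member_recs)
    rows = []
    categories = sorted({r.functional_category for r in member_recs})
    for cat in categories:
        in_cat = [r for r in member_recs if r.functional_category == cat]
        a = sum(r.on_array for r in in_cat)  # category & on array
        b = len(in_cat) - a  # category & off array
        c = n_array - a  # other & on array
        d = (n_members - len(in_cat)) - c  # other & off array
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "category": cat,
                "n_catalog": len(in_cat),
                "pct_catalog": 100.0 * len(in_cat) / n_members,
                "n_on_array": a,
                "pct_on_array": (100.0 * a / n_array) if n_array else float("nan"),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O: TSV annotation tables and catalog export


def read_annotations(path) -> list[GeneAnnotationRecord]:
    """Read a TSV annotation table.

    Columns: gene_id, compartment_terms (semicolon separated, may be empty),
    has_tm_domain, has_signal_peptide, functional_category, on_array.
    Missing predictions are read as false.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        terms = frozenset(t for t in row["compartment_terms"].split(";") if t)
        records.append(
            GeneAnnotationRecord(
                gene_id=row["gene_id"],
                compartment_terms=terms,
                has_tm_domain=_as_bool(row["has_tm_domain"]),
                has_signal_peptide=_as_bool(row["has_signal_peptide"]),
                functional_category=row["functional_category"] or "unclassified",
                on_array=_as_bool(row["on_array"]),
            )
        )
    return records


def _as_bool(s: str) -> bool:
    return str(s).strip().lower() in {"1", "true", "yes", "t"}


def write_catalog(catalog: MembranomeCatalog, path) -> None:
    """Write gene_id / member / reason as TSV."""
    df = pd.DataFrame(
        {
            "gene_id": sorted(catalog.evidence),
            "member": [g in catalog.members for g in sorted(catalog.evidence)],
            "reason": [catalog.evidence[g] for g in sorted(catalog.evidence)],
        }
    )
    df.to_csv(path, sep="\t", index=False)
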
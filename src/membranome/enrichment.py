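"""Gene-set enrichment of deregulated gene lists by Fisher's exact test.

Each set in a GMT collection is tested for over-representation in a gene
list with the one-sided hypergeometric tail on the 2x2 table
(in-list / not-in-list) x (in-set / not-in-set), restricted to the analyzed
gene universe.  p-values are reported uncorrected: the tested collections
overlap heavily, so the independence assumption behind standard
multiplicity corrections does not hold, and a reporting threshold
(default p < 0.05) is applied instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .mtdg import _log_hypergeom_tail
import math

__all__ = ["GeneSet", "GeneSetCollection", "read_gmt", "write_gmt", "enrich"]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    source: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        for sid, gs in self.sets.items():
            if not gs.members:
                raise ValueError(f"gene set {sid!r} has no members")


def read_gmt(path, source: str | None = None) -> GeneSetCollection:
    """Read a standard GMT file (name <tab> description <tab> members...).

    Sets with no members are dropped with a warning; duplicate set names
    and malformed lines are errors (with the line number).
    """
    if source is None:
        source = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed GMT line {lineno}")
            name, description, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene set name {name!r}")
            if not members:
                warnings.warn(f"{path}: line {lineno} set {name!r} is empty; dropped")
                continue
            sets[name] = GeneSet(
                set_id=name,
                name=name,
                source=source,
                description=description,
                members=frozenset(members),
            )
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(collection.sets):
            gs = collection.sets[sid]
            fh.write(
                "\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n"
            )


def enrich(
    gene_list,
    universe,
    collection: GeneSetCollection,
    p_threshold: float = 0.05,
    list_label: str = "",
) -> pd.DataFrame:
    """Fisher-exact enrichment of ``gene_list`` against every collection set.

    Collection genes absent from the universe are ignored; sets disjoint
    from the universe are omitted.  Rows with p < ``p_threshold`` are
    returned sorted by ascending p, uncorrected.
    """
    universe = set(universe)
    gene_list = set(gene_list)
    if gene_list - universe:
        raise ValueError("gene list must be a subset of the universe")
    if not gene_list:
        warnings.warn("empty gene list: no enrichment computed")
        return pd.DataFrame(
            columns=[
                "set_id", "source", "name", "p_value",
                "n_overlap", "overlap_genes", "list_label",
            ]
        )
    N, n = len(universe), len(gene_list)
    rows = []
    for sid in sorted(collection.sets):
        gs = collection.sets[sid]
        members = gs.members & universe
        if not members:
            continue
        overlap = gene_list & members
        logp = min(_log_hypergeom_tail(len(overlap), N, len(members), n), 0.0)
        p = math.exp(logp)
        if p < p_threshold:
            rows.append(
                {
                    "set_id": sid,
                    "source": gs.source,
                    "name": gs.name,
                    "p_value": p,
                    "n_overlap": len(overlap),
                    "overlap_genes": ";".join(sorted(overlap)),
                    "list_label": list_label,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "set_id", "source", "name", "p_value",
            "n_overlap", "overlap_genes", "list_label",
        ],
    )
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
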
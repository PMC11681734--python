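"""Translation of per-species gene abundances into human-ortholog space.

Cross-species expression comparison requires a shared gene space.  Orthology
between a species and human is in general many-to-many: when *m* genes of a
species share *n* human orthologs (m >= 0, n >= 1), the abundance of each of
the n human genes is taken to be the sum of the m species-gene abundances
divided by n.  The (m, n) groups are the connected components of the
bipartite orthology relation — the only partition under which "the m genes"
and "the n orthologs" are simultaneously well defined.  Redistribution
conserves abundance mass: each component contributes (S/n) x n = S.

Human genes with no ortholog in a species are not zero there — they are
unmeasured, and are flagged in the missing mask that the downstream screens
consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from xlps.data_io import ExpressionMatrix, FormatError, SampleSheet


@dataclass(frozen=True)
class OrthologMap:
    """Many-to-many orthology relation for one species against human."""

    species: str
    relations: frozenset[tuple[str, str]]  # (species_gene_id, human_gene_id)

    @classmethod
    def from_pairs(cls, species: str, pairs: Sequence[tuple[str, str]]) -> "OrthologMap":
        pair_list = [tuple(p) for p in pairs]
        rel = frozenset(pair_list)
        if len(rel) != len(pair_list):
            raise FormatError(f"duplicate ortholog pair(s) for species {species!r}")
        return cls(species, rel)

    @classmethod
    def read(cls, path: str | Path, species: str | None = None) -> "OrthologMap":
        """Read a two-column TSV: species_gene_id, human_gene_id."""
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        for col in ("species_gene_id", "human_gene_id"):
            if col not in df.columns:
                raise FormatError(f"ortholog map missing column {col!r}")
        name = species or Path(path).stem
        return cls.from_pairs(name, list(df[["species_gene_id", "human_gene_id"]].itertuples(index=False)))

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(sorted(self.relations), columns=["species_gene_id", "human_gene_id"])
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Component:
    """One connected component of the bipartite orthology graph."""

    species_genes: frozenset[str]
    human_genes: frozenset[str]


def build_components(omap: OrthologMap) -> list[Component]:
    """Connected components of the bipartite species-gene/human-gene relation.

    Union-find over the relation pairs; every pair ends up in exactly one
    component.  Returned in a deterministic order (by smallest human gene ID).
    """
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x: tuple[str, str]) -> tuple[str, str]:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def union(a: tuple[str, str], b: tuple[str, str]) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for sg, hg in omap.relations:
        for node in (("s", sg), ("h", hg)):
            parent.setdefault(node, node)
        union(("s", sg), ("h", hg))

    groups: dict[tuple[str, str], tuple[set[str], set[str]]] = {}
    for sg, hg in omap.relations:
        root = find(("s", sg))
        sset, hset = groups.setdefault(root, (set(), set()))
        sset.add(sg)
        hset.add(hg)
    comps = [Component(frozenset(s), frozenset(h)) for s, h in groups.values()]
    comps.sort(key=lambda c: min(c.human_genes))
    return comps


def translate(expr: ExpressionMatrix, omap: OrthologMap, human_universe: Sequence[str],
              warn_unquantified: bool = False) -> ExpressionMatrix:
    """Translate one species' TPM matrix into human-ortholog space.

    For every component with species-gene TPM sum S and n human orthologs,
    each of the n human genes receives S/n.  Mapped species genes absent from
    the quantification count as abundance 0 (annotation and quantification
    gene sets rarely coincide exactly).  Human genes of ``human_universe``
    outside every component are marked missing for all of this species'
    samples.
    """
    if expr.scale != "tpm":
        raise ValueError("translation is defined on TPM-scale abundances")
    comps = build_components(omap)
    seen_h: set[str] = set()
    for c in comps:
        overlap = seen_h & c.human_genes
        if overlap:
            raise FormatError(f"human gene(s) {sorted(overlap)} appear in two components")
        seen_h |= c.human_genes

    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    n_samples = len(expr.sample_ids)
    out = np.zeros((len(human_universe), n_samples))
    mask = np.ones((len(human_universe), n_samples), dtype=bool)
    h_index = {g: i for i, g in enumerate(human_universe)}

    unquantified: list[str] = []
    for comp in comps:
        rows = []
        for sg in comp.species_genes:
            i = gene_index.get(sg)
            if i is None:
                unquantified.append(sg)
            else:
                rows.append(i)
        total = expr.values[rows].sum(axis=0) if rows else np.zeros(n_samples)
        share = total / len(comp.human_genes)
        for hg in comp.human_genes:
            j = h_index.get(hg)
            if j is None:
                continue  # ortholog outside the requested universe
            out[j] = share
            mask[j] = False
    if unquantified and warn_unquantified:
        import warnings

        warnings.warn(
            f"{len(unquantified)} mapped {omap.species} gene(s) absent from quantification; "
            "treated as abundance 0",
            stacklevel=2,
        )
    return ExpressionMatrix(list(human_universe), list(expr.sample_ids), out, mask, scale="tpm")


def merge_species(matrices: Sequence[ExpressionMatrix], sheet: SampleSheet | None = None) -> ExpressionMatrix:
    """Column-concatenate per-species human-space matrices into one study matrix.

    All inputs must share the human universe (same gene IDs in the same
    order); sample IDs must be disjoint.  If a sheet is given, columns are
    reordered to the sheet's sample order.
    """
    if not matrices:
        raise ValueError("no matrices to merge")
    genes = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != genes:
            raise ValueError("matrices do not share the human universe ordering")
    all_samples: list[str] = []
    for m in matrices:
        all_samples.extend(m.sample_ids)
    if len(set(all_samples)) != len(all_samples):
        dups = sorted({s for s in all_samples if all_samples.count(s) > 1})
        raise ValueError(f"duplicated sample ID(s) across species: {dups}")
    values = np.hstack([m.values for m in matrices])
    mask = np.hstack([m.missing_mask for m in matrices])
    merged = ExpressionMatrix(list(genes), all_samples, values, mask, scale=matrices[0].scale)
    if sheet is not None:
        order = [s for s in sheet.sample_ids if s in set(all_samples)]
        merged = merged.subset_samples(order)
    return merged
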
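"""Complete-divergence screens: genes with no overlap between the groups.

A gene is *completely separated* when every measured value in one group
(baseline log2 expression, or per-individual log2 response) strictly exceeds
every measured value in the other group.  Because genome annotations are
incomplete, a single missing annotation is tolerated — but only in the more
strongly expressed (or induced) class: a missing measurement in the lower
class could hide an overlapping value, so it always breaks separation.  The
candidate higher class is decided by the group mean of the non-missing
values before the tolerance is applied.

Missingness from absent orthologs hits a whole species at a time, so the
tolerance is counted in *annotation units* (species by default in the
pipeline) rather than raw columns; with the default identity unit map every
column is its own unit, matching per-individual tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from xlps.de import DEResult


@dataclass(frozen=True)
class SeparationRecord:
    """Verdict of the complete-separation screen for one gene.

    ``gap`` is min(higher-class values) - max(lower-class values) on the
    analysis scale (positive iff separated); ``rank_score`` is the
    sensitive-minus-resilient difference of group means, used for top-k
    ranking.
    """

    gene_id: str
    separated: bool
    higher_class: str  # sensitive | resilient | none
    gap: float
    n_missing_higher: int
    n_missing_lower: int
    rank_score: float


def complete_separation_screen(values: np.ndarray, labels: Sequence[str],
                               missing: np.ndarray | None = None,
                               gene_ids: Sequence[str] | None = None,
                               tolerance: int = 1,
                               units: Sequence[str] | None = None) -> list[SeparationRecord]:
    """Screen a genes x individuals table for complete group separation.

    ``labels`` gives each column's group ('sensitive'/'resilient');
    ``missing`` marks unmeasured cells; ``units`` optionally maps columns to
    annotation units (e.g. species) in which missing entries are counted
    against the tolerance.  Genes with no measured value in either class are
    reported unseparated with ``higher_class='none'``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    unknown = set(labels) - {"sensitive", "resilient"}
    if unknown:
        raise ValueError(f"unlabeled or unknown group label(s): {sorted(unknown)}")
    if missing is None:
        missing = np.zeros(values.shape, dtype=bool)
    missing = np.asarray(missing, dtype=bool)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    if units is None:
        units = [str(j) for j in range(values.shape[1])]
    units = np.asarray(units)

    sens = labels == "sensitive"
    res = labels == "resilient"
    records: list[SeparationRecord] = []
    for i, gid in enumerate(gene_ids):
        obs = ~missing[i]
        stats_by_class = {}
        for name, cols in (("sensitive", sens), ("resilient", res)):
            v = values[i, cols & obs]
            miss_units = np.unique(units[cols & ~obs])
            stats_by_class[name] = (v, len(miss_units))
        v_s, miss_s = stats_by_class["sensitive"]
        v_r, miss_r = stats_by_class["resilient"]
        if v_s.size == 0 or v_r.size == 0:
            records.append(SeparationRecord(str(gid), False, "none", float("nan"),
                                            miss_s, miss_r, float("nan")))
            continue
        rank_score = float(v_s.mean() - v_r.mean())
        if v_s.mean() >= v_r.mean():
            higher, lower = "sensitive", "resilient"
            v_hi, v_lo, miss_hi, miss_lo = v_s, v_r, miss_s, miss_r
        else:
            higher, lower = "resilient", "sensitive"
            v_hi, v_lo, miss_hi, miss_lo = v_r, v_s, miss_r, miss_s
        gap = float(v_hi.min() - v_lo.max())
        separated = bool(gap > 0 and miss_hi <= tolerance and miss_lo == 0)
        records.append(SeparationRecord(str(gid), separated, higher,
                                        gap, miss_hi, miss_lo, rank_score))
    return records


def top_k_by_difference(records: Sequence[SeparationRecord], de: Sequence[DEResult] | None,
                        k: int, require_significant: bool = False) -> list[str]:
    """Rank separated genes by |group mean difference|, return the top k.

    With ``require_significant`` (the response-screen default), only genes
    whose corresponding differential test reached FDR <= cutoff are eligible.
    Ties break lexicographically by gene ID; if fewer than k genes qualify,
    the full qualifying list is returned.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    eligible = {r.gene_id: r for r in records if r.separated}
    if require_significant:
        if de is None:
            raise ValueError("require_significant needs the differential test results")
        sig = {d.gene_id for d in de if d.significant}
        eligible = {g: r for g, r in eligible.items() if g in sig}
    ordered = sorted(eligible.values(), key=lambda r: (-abs(r.rank_score), r.gene_id))
    return [r.gene_id for r in ordered[:k]]


def direction_census(records: Sequence[SeparationRecord],
                     gene_list: Sequence[str] | None = None) -> dict[str, int]:
    """Count how many screened genes are higher in each group.

    Restricted to ``gene_list`` when given (e.g. a top-k list); only
    separated genes are counted.
    """
    keep = set(gene_list) if gene_list is not None else None
    counts = {"sensitive": 0, "resilient": 0}
    for r in records:
        if not r.separated:
            continue
        if keep is not None and r.gene_id not in keep:
            continue
        counts[r.higher_class] += 1
    return counts


def screen_table(records: Sequence[SeparationRecord]) -> pd.DataFrame:
    """Records as a DataFrame in stable column order (for TSV output)."""
    return pd.DataFrame([{
        "gene_id": r.gene_id, "separated": r.separated, "higher_class": r.higher_class,
        "gap": r.gap, "n_missing_higher": r.n_missing_higher,
        "n_missing_lower": r.n_missing_lower, "rank_score": r.rank_score,
    } for r in records])
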
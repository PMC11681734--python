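"""Three-tier discrimination cascade for plasma and HDL proteome LFQ tables.

Plasma proteomes are compared between the sensitive and resilient species
groups by three mutually exclusive captures, applied in strict order:

1. **ANOVA tier** — proteins with enough detected values in both groups
   (default >= 2 per group) get a one-way ANOVA p-value across the two
   groups, with species as replicates; p < 0.05 captures the protein.  A
   protein that received a p-value exits the cascade whether or not it was
   captured.
2. **Fold-change tier** — proteins without a p-value but detected in both
   groups and in at least 4 species total are captured when the difference
   of group means of detected log2 LFQ values is at least 3.0 (|Δlog2| >= 3).
3. **Presence tier** — proteins detected in exactly one group are captured
   when detected in at least 3 species (necessarily all in that group).

The same cascade serves whole-plasma and HDL-associated protein tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from xlps.data_io import ProteinTable


@dataclass(frozen=True)
class TierConfig:
    """Capture thresholds of the three-tier cascade (defaults as used study-wide)."""

    anova_p_cutoff: float = 0.05
    log2fc_cutoff: float = 3.0
    min_occurrences: int = 4
    min_presence_species: int = 3
    min_values_per_group_for_anova: int = 2

    def __post_init__(self) -> None:
        if not (self.anova_p_cutoff > 0 and self.log2fc_cutoff > 0):
            raise ValueError("cutoffs must be positive")
        if min(self.min_occurrences, self.min_presence_species,
               self.min_values_per_group_for_anova) < 1:
            raise ValueError("minimum counts must be >= 1")


@dataclass(frozen=True)
class TierAssignment:
    """Cascade outcome for one protein: which tier (if any) captured it."""

    protein_id: str
    tier: str  # anova | foldchange | presence | none
    statistic: float | None = None  # p-value (anova) or group log2 fold change (foldchange)
    present_group: str | None = None  # for tier presence


def _group_values(table: ProteinTable, i: int) -> dict[str, np.ndarray]:
    out = {}
    for group in ("sensitive", "resilient"):
        cols = table.group_columns(group)
        det = table.detected[i, cols]
        out[group] = table.lfq[i, cols][det]
    return out


def _anova_p(v_s: np.ndarray, v_r: np.ndarray) -> float:
    """Two-group one-way ANOVA p-value with the zero-variance convention.

    Zero within-group variance with unequal means is maximal evidence of
    separation (p -> 0); zero variance with equal means is no evidence (p = 1).
    """
    if np.var(v_s) == 0 and np.var(v_r) == 0:
        return 0.0 if v_s.mean() != v_r.mean() else 1.0
    return float(stats.f_oneway(v_s, v_r).pvalue)


def tier1_anova(table: ProteinTable, cfg: TierConfig,
                indices: list[int] | None = None) -> tuple[list[TierAssignment], list[int]]:
    """ANOVA capture; returns (assignments for decided proteins, remainder indices)."""
    indices = list(range(len(table.protein_ids))) if indices is None else indices
    decided: list[TierAssignment] = []
    remainder: list[int] = []
    for i in indices:
        gv = _group_values(table, i)
        if all(len(v) >= cfg.min_values_per_group_for_anova for v in gv.values()):
            p = _anova_p(gv["sensitive"], gv["resilient"])
            tier = "anova" if p < cfg.anova_p_cutoff else "none"
            decided.append(TierAssignment(table.protein_ids[i], tier, statistic=p))
        else:
            remainder.append(i)
    return decided, remainder


def tier2_foldchange(table: ProteinTable, cfg: TierConfig,
                     indices: list[int]) -> tuple[list[TierAssignment], list[int]]:
    """Fold-change capture among proteins that had no ANOVA p-value."""
    decided: list[TierAssignment] = []
    remainder: list[int] = []
    for i in indices:
        gv = _group_values(table, i)
        n_s, n_r = len(gv["sensitive"]), len(gv["resilient"])
        if n_s == 0 or n_r == 0:
            remainder.append(i)  # one-group proteins fall through to presence
            continue
        if n_s + n_r < cfg.min_occurrences:
            decided.append(TierAssignment(table.protein_ids[i], "none"))
            continue
        fc = float(gv["sensitive"].mean() - gv["resilient"].mean())
        tier = "foldchange" if abs(fc) >= cfg.log2fc_cutoff else "none"
        decided.append(TierAssignment(table.protein_ids[i], tier, statistic=fc))
    return decided, remainder


def tier3_presence(table: ProteinTable, cfg: TierConfig,
                   indices: list[int]) -> list[TierAssignment]:
    """Presence/absence capture among proteins detected in one group only."""
    decided: list[TierAssignment] = []
    for i in indices:
        gv = _group_values(table, i)
        n_s, n_r = len(gv["sensitive"]), len(gv["resilient"])
        if n_s > 0 and n_r > 0:  # defensive; cascade routing prevents this
            decided.append(TierAssignment(table.protein_ids[i], "none"))
            continue
        n_det, group = (n_s, "sensitive") if n_s > 0 else (n_r, "resilient")
        if n_det >= cfg.min_presence_species:
            decided.append(TierAssignment(table.protein_ids[i], "presence", present_group=group))
        else:
            decided.append(TierAssignment(table.protein_ids[i], "none"))
    return decided


def run_cascade(table: ProteinTable, cfg: TierConfig | None = None
                ) -> tuple[list[TierAssignment], dict[str, int]]:
    """Run all three tiers in order; every protein gets exactly one assignment.

    Returns (assignments in the table's protein order, per-tier counts).
    """
    cfg = cfg or TierConfig()
    t1, rem1 = tier1_anova(table, cfg)
    t2, rem2 = tier2_foldchange(table, cfg, rem1)
    t3 = tier3_presence(table, cfg, rem2)
    by_id = {a.protein_id: a for a in (*t1, *t2, *t3)}
    assignments = [by_id[p] for p in table.protein_ids]
    counts = {"anova": 0, "foldchange": 0, "presence": 0, "none": 0}
    for a in assignments:
        counts[a.tier] += 1
    return assignments, counts


def tier_table(assignments: list[TierAssignment]) -> pd.DataFrame:
    """Assignments as a DataFrame in stable column order (for TSV output)."""
    return pd.DataFrame([{
        "protein_id": a.protein_id, "tier": a.tier,
        "statistic": a.statistic if a.statistic is not None else float("nan"),
        "present_group": a.present_group or "NA",
    } for a in assignments])
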
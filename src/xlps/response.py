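"""Paired LPS-response analysis and the between-group response-difference test.

The response of a gene in an individual is the log2 ratio of its abundance
in the stimulated sample to its paired unstimulated (dose 0) sample from the
same individual at the same incubation time, each offset by the pseudocount:
log2(TPM_dose + pc) - log2(TPM_0 + pc).  Ratios are taken on the TPM scale
(not on normalized values) because the response is defined as a fold change
in TPM within an individual; the within-pair design already removes
individual- and depth-level offsets.

Per species, genes are tested for a nonzero mean response across individuals
with an empirical-Bayes moderated one-sample t (fold >= 2, FDR <= 0.05 by
default).  Between groups, the per-individual fold changes are fed to the
same blocked moderated machinery as the baseline test, with the
difference-in-fold-changes threshold 1.5-fold and FDR <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from xlps.data_io import ExpressionMatrix, SampleSheet
from xlps.de import DEConfig, DEResult, bh_fdr, ebayes_shrink_variances, moderated_group_test


@dataclass(frozen=True)
class ResponseConfig:
    """Dose and thresholds for the LPS-response analyses.

    The default dose is 10 ng/mL — dose escalation to 100 and 1000 ng/mL has
    only a minimal additional effect, so the lowest stimulating dose carries
    the comparisons.  per_species_fold_cutoff gates the within-species
    response test; group_diff_fold_cutoff gates the between-group
    difference-in-fold-changes test.  Both are linear-scale folds.
    """

    dose: float = 10.0
    per_species_fold_cutoff: float = 2.0
    group_diff_fold_cutoff: float = 1.5
    fdr_cutoff: float = 0.05
    pseudocount: float = 1.0
    min_individuals: int = 3

    def __post_init__(self) -> None:
        if not (self.per_species_fold_cutoff > 1 and self.group_diff_fold_cutoff > 1):
            raise ValueError("fold cutoffs must exceed 1")
        if not 0 < self.fdr_cutoff < 1:
            raise ValueError("fdr_cutoff must lie in (0, 1)")


@dataclass(frozen=True)
class FoldChangeRecord:
    """One individual's log2 response of one gene at one dose and time."""

    gene_id: str
    species: str
    individual: str
    time: float
    log2fc: float


def paired_fold_changes(matrix: ExpressionMatrix, sheet: SampleSheet,
                        cfg: ResponseConfig | None = None,
                        time: float = 6.0) -> pd.DataFrame:
    """Per-individual log2 fold changes (stimulated vs paired control) at one time.

    ``matrix`` must be TPM-scale over (at least) the samples of ``sheet``.
    Returns a long-format table with columns gene_id, species, group,
    individual, time, log2fc; a row exists only where both pair members are
    measured (genes without an ortholog in a species yield no rows for it).
    """
    cfg = cfg or ResponseConfig()
    if matrix.scale != "tpm":
        raise ValueError("paired fold changes are defined on TPM-scale abundances")
    f = sheet.frame
    stim = f[(f["dose"] == cfg.dose) & (f["time"] == time)]
    ctrl = f[(f["dose"] == 0) & (f["time"] == time)]
    if stim.empty:
        raise ValueError(f"no samples at dose {cfg.dose} ng/mL, time {time} h")
    ctrl_ids = {(r.species, r.individual): r.sample_id for r in ctrl.itertuples()}

    col = {s: j for j, s in enumerate(matrix.sample_ids)}
    frames = []
    genes = np.asarray(matrix.gene_ids)
    for r in stim.itertuples():
        key = (r.species, r.individual)
        if key not in ctrl_ids or r.sample_id not in col or ctrl_ids[key] not in col:
            continue
        js, jc = col[r.sample_id], col[ctrl_ids[key]]
        both = ~(matrix.missing_mask[:, js] | matrix.missing_mask[:, jc])
        lfc = np.log2(matrix.values[both, js] + cfg.pseudocount) - \
            np.log2(matrix.values[both, jc] + cfg.pseudocount)
        frames.append(pd.DataFrame({
            "gene_id": genes[both], "species": r.species, "group": r.group,
            "individual": r.individual, "time": time, "log2fc": lfc,
        }))
    if not frames:
        raise ValueError(f"no stimulated/control pairs at dose {cfg.dose}, time {time}")
    return pd.concat(frames, ignore_index=True)


def _records_to_matrix(records: pd.DataFrame) -> tuple[list[str], pd.DataFrame, np.ndarray, np.ndarray]:
    """Pivot long-format fold-change records to genes x individuals with a mask."""
    records = records.assign(col=records["species"].astype(str) + "/" + records["individual"].astype(str))
    wide = records.pivot_table(index="gene_id", columns="col", values="log2fc", aggfunc="mean")
    meta = records.drop_duplicates("col").set_index("col").loc[wide.columns]
    values = wide.to_numpy()
    mask = ~np.isfinite(values)
    return list(wide.index), meta, np.where(mask, 0.0, values), mask


def per_species_de(records: pd.DataFrame, cfg: ResponseConfig | None = None,
                   moderate: bool = True) -> list[DEResult]:
    """Moderated one-sample test of mean log2 response != 0 for one species.

    ``records`` is the long table of :func:`paired_fold_changes` restricted to
    one species.  Genes with fewer than ``cfg.min_individuals`` paired
    individuals are excluded with a reason.  The t statistic is the mean
    response over individuals divided by its moderated standard error; the
    ``log2fc`` field of each result is that mean response, and ``direction``
    reads higher_in_sensitive-style induced/repressed semantics: positive
    means induced by LPS.
    """
    cfg = cfg or ResponseConfig()
    if records["species"].nunique() != 1:
        raise ValueError("per_species_de expects records from a single species")
    gene_ids, _meta, values, mask = _records_to_matrix(records)
    n = (~mask).sum(axis=1).astype(float)
    total = np.where(mask, 0.0, values).sum(axis=1)
    mean = np.divide(total, n, out=np.zeros_like(total), where=n > 0)
    dev2 = np.where(mask, 0.0, (values - mean[:, None]) ** 2).sum(axis=1)
    df = n - 1.0
    s2 = np.divide(dev2, df, out=np.full_like(dev2, np.nan), where=df > 0)

    tested = n >= cfg.min_individuals
    if moderate:
        d0, _s0, s2_post = ebayes_shrink_variances(s2[tested], df[tested])
        df_total = df[tested] + d0
    else:
        s2_post, df_total = s2[tested], df[tested]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = mean[tested] / np.sqrt(s2_post / n[tested])
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)
    big = ~np.isfinite(t_stat)
    p = 2.0 * stats.t.sf(np.abs(np.where(big, 0.0, t_stat)),
                         np.where(np.isfinite(df_total), df_total, 1e12))
    p[big] = 0.0
    fdr = bh_fdr(p)

    cutoff = np.log2(cfg.per_species_fold_cutoff)
    out: list[DEResult] = []
    ti = 0
    for i, gid in enumerate(gene_ids):
        if tested[i]:
            m = float(mean[i])
            out.append(DEResult(
                gene_id=gid, log2fc=m, moderated_t=float(t_stat[ti]),
                p_value=float(p[ti]), fdr=float(fdr[ti]),
                significant=bool(abs(m) >= cutoff and fdr[ti] <= cfg.fdr_cutoff),
                direction="higher_in_sensitive" if m >= 0 else "higher_in_resilient",
                n_samples_used=int(n[i]),
            ))
            ti += 1
        else:
            out.append(DEResult(
                gene_id=gid, log2fc=float("nan"), moderated_t=float("nan"),
                p_value=float("nan"), fdr=float("nan"), significant=False,
                direction=None, n_samples_used=int(n[i]),
                exclusion_reason="insufficient_paired_individuals",
            ))
    return out


def group_response_difference(records: pd.DataFrame, sheet: SampleSheet,
                              cfg: ResponseConfig | None = None,
                              moderate: bool = True) -> list[DEResult]:
    """Sensitive-vs-resilient contrast of per-individual log2 fold changes.

    Feeds the fold-change table of all species into the blocked moderated
    group test (species as blocks, compound-symmetry GLS, empirical-Bayes
    shrinkage).  Significance requires a difference in fold changes of at
    least ``group_diff_fold_cutoff`` (default 1.5-fold) at the FDR cutoff.
    """
    cfg = cfg or ResponseConfig()
    gene_ids, meta, values, mask = _records_to_matrix(records)
    de_cfg = DEConfig(fold_cutoff=cfg.group_diff_fold_cutoff, fdr_cutoff=cfg.fdr_cutoff,
                      pseudocount=cfg.pseudocount)
    return moderated_group_test(values, mask, gene_ids,
                                meta["group"].to_numpy(), meta["species"].to_numpy(),
                                de_cfg, moderate=moderate)
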
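"""Normalization and the baseline sensitive-vs-resilient differential test.

The baseline contrast asks, gene by gene, whether unstimulated whole-blood
leukocyte expression differs between LPS-sensitive and LPS-resilient species.
Samples are log2(TPM + pseudocount), quantile normalized, and tested with a
linear model in which group is the fixed effect and the blocking unit
(species by default) carries a random intercept.  The random effect is
handled as in the duplicate-correlation approach: a single consensus
intra-block correlation rho is estimated across genes, and each gene is fit
by generalized least squares under a compound-symmetry covariance with that
rho.  Residual variances are then shrunk toward a pooled prior by empirical
Bayes — the scaled-F / inverse-chi-square model in which the posterior
variance is (d0*s0^2 + d*s^2)/(d0 + d) — and the moderated t statistic is
referred to a t distribution on d0 + d degrees of freedom.  Multiplicity is
controlled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from xlps.data_io import ExpressionMatrix, SampleSheet


@dataclass(frozen=True)
class DEConfig:
    """Thresholds and transforms for the group differential test.

    fold_cutoff is on the linear scale (default 2-fold); fdr_cutoff is the
    Benjamini-Hochberg level (default 0.05); pseudocount is added to TPM
    before the log2 transform; block_on selects the random-intercept unit.
    """

    fold_cutoff: float = 2.0
    fdr_cutoff: float = 0.05
    pseudocount: float = 1.0
    block_on: str = "species"
    baseline_time: float = 2.0

    def __post_init__(self) -> None:
        if not self.fold_cutoff > 1:
            raise ValueError("fold_cutoff must exceed 1")
        if not 0 < self.fdr_cutoff < 1:
            raise ValueError("fdr_cutoff must lie in (0, 1)")
        if self.block_on not in ("species", "individual"):
            raise ValueError("block_on must be 'species' or 'individual'")


@dataclass
class DEResult:
    """Per-gene outcome of a sensitive-vs-resilient contrast.

    log2fc is the sensitive-minus-resilient difference of group means on the
    analysis (log2) scale; direction is derived from its sign.  Genes that
    could not be tested carry an exclusion_reason and NaN statistics.
    """

    gene_id: str
    log2fc: float
    moderated_t: float
    p_value: float
    fdr: float
    significant: bool
    direction: str | None
    n_samples_used: int = 0
    exclusion_reason: str | None = None


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (mean-of-sorted-columns) distribution.

    Missing cells are excluded from each column's rank pool.  Each column's
    non-missing values are replaced by the reference distribution evaluated at
    their quantiles; ties (average ranks) receive the mean of their target
    quantiles via linear interpolation.  When all columns have equal depth the
    reference is exactly the per-rank mean of the sorted columns and the
    operation is exactly idempotent.
    """
    if matrix.scale != "log2":
        raise ValueError("quantile normalization expects a log2-scale matrix")
    vals = np.where(matrix.missing_mask, np.nan, matrix.values)
    n_obs = (~matrix.missing_mask).sum(axis=0)
    if (n_obs < 2).any():
        bad = [matrix.sample_ids[j] for j in np.nonzero(n_obs < 2)[0]]
        raise ValueError(f"column(s) with fewer than 2 non-missing values: {bad}")
    n_ref = int(n_obs.max())
    grid = (np.arange(n_ref) + 0.5) / n_ref

    ref = np.zeros(n_ref)
    for j in range(vals.shape[1]):
        col = np.sort(vals[~matrix.missing_mask[:, j], j])
        k = col.size
        qpoints = (np.arange(k) + 0.5) / k
        ref += np.interp(grid, qpoints, col)
    ref /= vals.shape[1]

    out = matrix.values.copy()
    for j in range(vals.shape[1]):
        obs = ~matrix.missing_mask[:, j]
        col = vals[obs, j]
        k = col.size
        ranks = stats.rankdata(col, method="average")
        out[obs, j] = np.interp((ranks - 0.5) / k, grid, ref)
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), out,
                            matrix.missing_mask.copy(), scale="log2")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if -dif / y < 1e-10:
            break
    return y


def ebayes_shrink_variances(s2: np.ndarray, df: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Estimate (d0, s0^2) of the scaled-F variance model and shrink s^2.

    Hyperparameters are fit by matching the first two moments of log s^2
    under the model s^2 ~ s0^2 * F(df, d0), using digamma/trigamma identities.
    Returns (d0, s0^2, posterior variances); d0 = inf means complete pooling.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & np.isfinite(df) & (df > 0)
    if ok.sum() < 2:
        # Too few informative genes to pool: no moderation.
        return 0.0, float(np.nanmedian(s2[ok])) if ok.any() else 1.0, s2.copy()
    z = np.log(s2[ok])
    e = z - digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(polygamma(1, df[ok] / 2.0)))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    s2_filled = np.where(np.isfinite(s2), s2, 0.0)
    if np.isinf(d0):
        post = np.full_like(s2_filled, s0_2)
    else:
        post = (d0 * s0_2 + df * s2_filled) / (d0 + df)
    return d0, s0_2, post


def _chi2_trimmed_mean_factor(df: float, trim: float) -> float:
    """E[trimmed mean] of a chi-square(df)/df variable (identity: E[X 1(X<b)] via df+2)."""
    if not np.isfinite(df) or df <= 0:
        return 1.0
    a, b = stats.chi2.ppf([trim, 1.0 - trim], df)
    frac = stats.chi2.cdf(b, df + 2.0) - stats.chi2.cdf(a, df + 2.0)
    return float(frac / (1.0 - 2.0 * trim))


def estimate_consensus_correlation(values: np.ndarray, mask: np.ndarray,
                                   groups: np.ndarray, blocks: np.ndarray,
                                   trim: float = 0.15) -> float:
    """Consensus intra-block correlation across genes.

    Per gene, the one-way decomposition of residuals (group means removed)
    into between- and within-block mean squares yields unbiased
    variance-component estimates, with the unbalanced-design correction for
    the effective block size.  The consensus is formed from trimmed means of
    the per-gene mean squares rather than from per-gene correlation ratios
    (whose average carries a downward Jensen bias); each trimmed mean is
    rescaled by the exact expected trimmed mean of a chi-square/df variable
    at the design's degrees of freedom, so the estimator is Fisher-consistent
    under a shared correlation while trimming keeps it robust to outlying
    genes.
    """
    uniq_blocks = np.unique(blocks)
    uniq_groups = np.unique(groups)
    obs = ~mask
    n_g = obs.sum(axis=1).astype(float)

    # residuals after removing per-group means (per gene, missing-aware)
    resid = np.where(obs, values, 0.0)
    for g in uniq_groups:
        cols = groups == g
        cnt = obs[:, cols].sum(axis=1)
        tot = np.where(obs[:, cols], values[:, cols], 0.0).sum(axis=1)
        mean = np.divide(tot, cnt, out=np.zeros_like(tot), where=cnt > 0)
        resid[:, cols] = np.where(obs[:, cols], values[:, cols] - mean[:, None], 0.0)

    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    sum_n2 = np.zeros(values.shape[0])
    n_blocks_used = np.zeros(values.shape[0])
    for b in uniq_blocks:
        cols = blocks == b
        n_b = obs[:, cols].sum(axis=1).astype(float)
        s_b = resid[:, cols].sum(axis=1)
        ss_b = (resid[:, cols] ** 2).sum(axis=1)
        m_b = np.divide(s_b, n_b, out=np.zeros_like(s_b), where=n_b > 0)
        ssb += n_b * m_b**2
        ssw += ss_b - n_b * m_b**2
        sum_n2 += n_b**2
        n_blocks_used += (n_b > 0).astype(float)

    df_b = n_blocks_used - len(uniq_groups)
    df_w = n_g - n_blocks_used
    ok = (df_b >= 1) & (df_w >= 1) & (n_g > n_blocks_used)
    if not ok.any():
        return 0.0
    msb = ssb[ok] / df_b[ok]
    msw = ssw[ok] / df_w[ok]
    n0 = (n_g[ok] - sum_n2[ok] / n_g[ok]) / np.maximum(n_blocks_used[ok] - 1, 1.0)
    n0 = np.maximum(n0, 1.0 + 1e-12)
    msb_c = float(stats.trim_mean(msb, trim)) / _chi2_trimmed_mean_factor(float(np.median(df_b[ok])), trim)
    msw_c = float(stats.trim_mean(msw, trim)) / _chi2_trimmed_mean_factor(float(np.median(df_w[ok])), trim)
    n0_bar = float(np.mean(n0))
    denom = msb_c + (n0_bar - 1.0) * msw_c
    if denom <= 0:
        return 0.0
    return float(np.clip((msb_c - msw_c) / denom, -0.98, 0.98))


def _gls_group_contrast(values: np.ndarray, mask: np.ndarray, groups: np.ndarray,
                        blocks: np.ndarray, rho: float,
                        min_blocks_per_group: int = 2):
    """Per-gene GLS fit of the two group means under compound symmetry.

    Returns (log2fc, se_unscaled^2, s2, df, n_used, reason) arrays; the
    contrast is group[0]-coded ``sensitive`` minus ``resilient``.
    """
    n_genes = values.shape[0]
    obs = ~mask
    uniq_blocks = np.unique(blocks)
    block_group = {b: groups[blocks == b][0] for b in uniq_blocks}

    # per-block sufficient statistics, vectorized over genes
    n_b = np.stack([obs[:, blocks == b].sum(axis=1) for b in uniq_blocks], axis=1).astype(float)
    s_b = np.stack([np.where(obs[:, blocks == b], values[:, blocks == b], 0.0).sum(axis=1)
                    for b in uniq_blocks], axis=1)
    ss_b = np.stack([(np.where(obs[:, blocks == b], values[:, blocks == b], 0.0) ** 2).sum(axis=1)
                     for b in uniq_blocks], axis=1)

    w = np.divide(n_b, 1.0 + (n_b - 1.0) * rho, out=np.zeros_like(n_b), where=n_b > 0)
    m_b = np.divide(s_b, n_b, out=np.zeros_like(s_b), where=n_b > 0)

    is_sens = np.array([block_group[b] == "sensitive" for b in uniq_blocks])
    mu = np.zeros((n_genes, 2))
    W = np.zeros((n_genes, 2))
    blocks_in_group = np.zeros((n_genes, 2))
    for gi, sel in enumerate((is_sens, ~is_sens)):
        W[:, gi] = w[:, sel].sum(axis=1)
        blocks_in_group[:, gi] = (n_b[:, sel] > 0).sum(axis=1)
        num = (w[:, sel] * m_b[:, sel]).sum(axis=1)
        mu[:, gi] = np.divide(num, W[:, gi], out=np.zeros_like(num), where=W[:, gi] > 0)

    fitted = np.where(is_sens[None, :], mu[:, [0]], mu[:, [1]])
    # whitened residual sum of squares under (1-rho) I + rho J per block
    rbar = m_b - fitted
    sse_raw = ss_b - 2.0 * fitted * s_b + n_b * fitted**2
    shrink = np.divide(rho * n_b**2 * rbar**2, 1.0 + (n_b - 1.0) * rho,
                       out=np.zeros_like(n_b), where=n_b > 0)
    sse = ((sse_raw - shrink) / (1.0 - rho)).sum(axis=1)

    n_used = n_b.sum(axis=1)
    df = n_used - 2.0
    log2fc = mu[:, 0] - mu[:, 1]
    v_unscaled = np.divide(1.0, W[:, 0], out=np.full(n_genes, np.inf), where=W[:, 0] > 0) + \
        np.divide(1.0, W[:, 1], out=np.full(n_genes, np.inf), where=W[:, 1] > 0)
    s2 = np.divide(sse, df, out=np.full(n_genes, np.nan), where=df > 0)
    s2 = np.maximum(s2, 0.0)

    reason = np.full(n_genes, None, dtype=object)
    reason[(blocks_in_group[:, 0] == 0) | (blocks_in_group[:, 1] == 0)] = "missing_in_group"
    few = (blocks_in_group < min_blocks_per_group).any(axis=1) & (reason == None)  # noqa: E711
    reason[few] = "insufficient_blocks"
    reason[(df <= 0) & (reason == None)] = "insufficient_samples"  # noqa: E711
    return log2fc, v_unscaled, s2, df, n_used.astype(int), reason


def moderated_group_test(values: np.ndarray, mask: np.ndarray, gene_ids: Sequence[str],
                         groups: Sequence[str], blocks: Sequence[str], cfg: DEConfig,
                         effect_cutoff_log2: float | None = None,
                         moderate: bool = True) -> list[DEResult]:
    """Sensitive-vs-resilient moderated test on an arbitrary response table.

    ``values`` is genes x observations on the analysis scale (log2 expression
    for the baseline test, per-individual log2 fold changes for the response
    difference test); ``groups``/``blocks`` label the observation columns.
    ``moderate=False`` skips the empirical-Bayes step and reports plain GLS t
    statistics (the d0 -> 0 limit).
    """
    groups = np.asarray(groups)
    blocks = np.asarray(blocks)
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    for g in ("sensitive", "resilient"):
        if len(np.unique(blocks[groups == g])) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 blocks; random effect inestimable")

    rho = estimate_consensus_correlation(values, mask, groups, blocks)
    log2fc, v, s2, df, n_used, reason = _gls_group_contrast(values, mask, groups, blocks, rho)

    tested = reason == None  # noqa: E711
    if moderate:
        d0, _s0, s2_post = ebayes_shrink_variances(s2[tested], df[tested])
        df_total = df[tested] + d0
    else:
        s2_post = s2[tested]
        df_total = df[tested]

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = log2fc[tested] / np.sqrt(s2_post * v[tested])
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)
    big = ~np.isfinite(t_stat)
    finite_df = np.where(np.isfinite(df_total), df_total, 1e12)
    p = 2.0 * stats.t.sf(np.abs(np.where(big, 0.0, t_stat)), finite_df)
    p[big] = 0.0
    fdr = bh_fdr(p)

    cutoff = np.log2(cfg.fold_cutoff) if effect_cutoff_log2 is None else effect_cutoff_log2
    results: list[DEResult] = []
    ti = 0
    for i, gid in enumerate(gene_ids):
        if tested[i]:
            fc = float(log2fc[i])
            sig = bool(abs(fc) >= cutoff and fdr[ti] <= cfg.fdr_cutoff)
            results.append(DEResult(
                gene_id=str(gid), log2fc=fc, moderated_t=float(t_stat[ti]),
                p_value=float(p[ti]), fdr=float(fdr[ti]), significant=sig,
                direction="higher_in_sensitive" if fc >= 0 else "higher_in_resilient",
                n_samples_used=int(n_used[i]),
            ))
            ti += 1
        else:
            results.append(DEResult(
                gene_id=str(gid), log2fc=float("nan"), moderated_t=float("nan"),
                p_value=float("nan"), fdr=float("nan"), significant=False,
                direction=None, n_samples_used=int(n_used[i]),
                exclusion_reason=str(reason[i]),
            ))
    return results


def fit_blocked_moderated_test(matrix: ExpressionMatrix, sheet: SampleSheet,
                               cfg: DEConfig | None = None,
                               moderate: bool = True) -> list[DEResult]:
    """Baseline group contrast on a log2 matrix restricted to baseline samples.

    ``matrix`` columns must all appear in ``sheet``; each sample carries its
    species' group label and its block (species by default, individual if
    configured).  See :func:`moderated_group_test` for the model.
    """
    cfg = cfg or DEConfig()
    if matrix.scale != "log2":
        raise ValueError("fit_blocked_moderated_test expects a log2-scale matrix")
    meta = sheet.frame.set_index("sample_id").loc[matrix.sample_ids]
    groups = meta["group"].to_numpy()
    blocks = meta[cfg.block_on].to_numpy()
    if cfg.block_on == "individual":
        blocks = (meta["species"].astype(str) + "/" + meta["individual"].astype(str)).to_numpy()
    return moderated_group_test(matrix.values, matrix.missing_mask, matrix.gene_ids,
                                groups, blocks, cfg, moderate=moderate)


def pca_overview(matrix: ExpressionMatrix, sheet: SampleSheet | None = None,
                 n_components: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space PCA of a log2 matrix for a study overview plot.

    Missing cells are mean-imputed per gene (this overview only; tests and
    screens consume the mask directly).  Sign convention: the
    largest-magnitude gene loading of each component is made positive, so
    coordinates are deterministic.  Returns (samples x PCs table, explained
    variance fractions).
    """
    from sklearn.decomposition import PCA

    vals = np.where(matrix.missing_mask, np.nan, matrix.values)
    gene_means = np.nanmean(vals, axis=1)
    gene_means = np.where(np.isfinite(gene_means), gene_means, 0.0)
    filled = np.where(np.isnan(vals), gene_means[:, None], vals)
    X = filled.T  # samples x genes
    k = min(n_components, X.shape[0], X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1.0
    table = pd.DataFrame(coords, index=matrix.sample_ids,
                         columns=[f"PC{i + 1}" for i in range(k)])
    if sheet is not None:
        meta = sheet.frame.set_index("sample_id").loc[matrix.sample_ids]
        table = table.assign(species=meta["species"].to_numpy(), group=meta["group"].to_numpy())
    return table, pca.explained_variance_ratio_
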
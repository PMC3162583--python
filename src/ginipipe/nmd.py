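"""GINI differential-expression calling from two-color NMD-inhibition arrays.

Each individual contributes one two-channel array: the treated (NMD-blocked)
channel r against the untreated channel g.  The per-probe response is the
background-adjusted natural log-ratio ln(r/g); log-ratios are quantile
normalized between arrays, and each gene in the region of interest is fitted
with a linear mixed model

    y_fi = mu + beta * affected_fi + u_f + e_fi,
    u_f ~ N(0, sigma2_family),  e_fi ~ N(0, sigma2_resid),

with affection status as the fixed contrast and the sibship as a random
intercept.  A gene is called when the status estimate is positive and its
t-test p-value falls under the cut-off (default alpha = 0.025, one gene at a
time, no multiplicity correction); a fold-change threshold, a genomic-band
whitelist and a stress-response exclusion list refine the call set.

The variance components are estimated by REML, profiled over the ratio
sigma2_family / sigma2_resid, and the t statistic uses the containment
degrees of freedom n_families - 1, which is exact for the balanced
one-affected/one-healthy sibling design (where the fit coincides with the
paired t-test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LogRatioMatrix",
    "MixedModelFit",
    "DECall",
    "background_adjust",
    "log_ratio",
    "build_logratio_matrix",
    "quantile_normalize",
    "filter_region",
    "fit_family_lmm",
    "fit_all_genes",
    "select_de_genes",
    "run_nmd_de",
]


@dataclass
class LogRatioMatrix:
    """Normalized ln(treated/untreated) ratios, genes x individuals."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame  # index: sample_id; columns family_id, affected
    gene_meta: pd.DataFrame  # index: gene/probe id; column band

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("log-ratio matrix contains missing values")


@dataclass(frozen=True)
class MixedModelFit:
    beta_hat: float
    se_beta: float
    t_stat: float
    df: float
    p_value: float
    sigma2_family: float
    sigma2_resid: float
    mu_hat: float
    boundary: bool = False  # True when the family variance hit zero


@dataclass(frozen=True)
class DECall:
    gene_id: str
    beta_hat: float
    p_value: float
    fold_change: float
    selected: bool
    reason: str  # p_only | p_and_fc | location | excluded_stress | not_selected


def background_adjust(
    foreground: np.ndarray | pd.Series | float,
    background: np.ndarray | pd.Series | float,
    floor: float = 1.0,
) -> np.ndarray | float:
    """Subtract the per-probe background, flooring at a small positive value.

    The floor keeps downstream log-ratios defined when background exceeds
    foreground on weak probes.
    """
    fg = np.asarray(foreground, dtype=float)
    bg = np.asarray(background, dtype=float)
    if np.any(fg < 0) or np.any(bg < 0):
        raise ValueError("raw intensities must be non-negative")
    out = np.maximum(fg - bg, floor)
    return out if out.ndim else float(out)


def log_ratio(r_adjusted, g_adjusted) -> np.ndarray | float:
    """Natural log of the treated/untreated intensity ratio."""
    r = np.asarray(r_adjusted, dtype=float)
    g = np.asarray(g_adjusted, dtype=float)
    out = np.log(r / g)
    return out if out.ndim else float(out)


def build_logratio_matrix(samples, floor: float = 1.0) -> LogRatioMatrix:
    """Assemble per-sample two-color records into a gene x sample log-ratio matrix.

    ``samples`` is an iterable of :class:`ginipipe.simulate.ArraySample`
    (or anything with ``sample_id``, ``family_id``, ``affected`` and a
    ``records`` frame holding the standard two-color columns).
    """
    cols = {}
    meta_rows = []
    gene_meta = None
    for s in samples:
        rec = s.records
        r = background_adjust(rec["rMeanSignal"], rec["rBGMedianSignal"], floor)
        g = background_adjust(rec["gMeanSignal"], rec["gBGMedianSignal"], floor)
        cols[s.sample_id] = pd.Series(log_ratio(r, g), index=rec["ProbeName"].to_numpy())
        meta_rows.append(
            {"sample_id": s.sample_id, "family_id": s.family_id, "affected": s.affected}
        )
        if gene_meta is None:
            gene_meta = pd.DataFrame(
                {"gene_id": rec["GeneName"].to_numpy(), "band": rec["Band"].to_numpy()},
                index=rec["ProbeName"].to_numpy(),
            )
    values = pd.DataFrame(cols)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return LogRatioMatrix(values=values, sample_meta=meta, gene_meta=gene_meta)


def quantile_normalize(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Between-array quantile normalization.

    Every column is mapped onto the reference distribution formed by the
    row-wise mean of the sorted columns; tied values within a column receive
    the mean of the reference values at their tied ranks, and the original
    row order is preserved.
    """
    is_df = isinstance(values, pd.DataFrame)
    x = values.to_numpy(dtype=float) if is_df else np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two columns")
    if np.isnan(x).any():
        raise ValueError("missing values are not supported")
    reference = np.mean(np.sort(x, axis=0), axis=1)
    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n)
        mapped[order] = reference
        # ties: average the reference values assigned within each tied group
        sorted_col = col[order]
        start = 0
        while start < n:
            end = start
            while end + 1 < n and sorted_col[end + 1] == sorted_col[start]:
                end += 1
            if end > start:
                mapped[order[start : end + 1]] = reference[start : end + 1].mean()
            start = end + 1
        out[:, j] = mapped
    if is_df:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def filter_region(matrix: LogRatioMatrix, band_whitelist) -> LogRatioMatrix:
    """Keep probes whose cytogenetic band starts with any whitelist entry.

    Matching is case-insensitive and prefix-based ("Xq27" matches "Xq27.1");
    an empty whitelist disables the filter.
    """
    patterns = [str(b).lower() for b in band_whitelist]
    if not patterns:
        return matrix
    bands = matrix.gene_meta["band"].astype(str).str.lower()
    keep = bands.apply(lambda b: any(b.startswith(p) for p in patterns))
    if not keep.any():
        warnings.warn("region filter retained no probes")
    return LogRatioMatrix(
        values=matrix.values.loc[keep.to_numpy()],
        sample_meta=matrix.sample_meta,
        gene_meta=matrix.gene_meta.loc[keep.to_numpy()],
    )


def _reml_pieces(y, x_affected, fam_sizes, fam_slices, lam):
    """Profiled REML quantities for variance ratio lam = s2_family/s2_resid.

    The covariance is W = I + lam * ZZ' with Z the family indicator; W is
    block diagonal and each block inverse is I - lam/(1 + lam n_f) J.
    Returns (-2 restricted log-likelihood up to constants, beta vector,
    (X'W^-1X)^-1, residual quadratic form).
    """
    n = y.size
    X = np.column_stack([np.ones(n), x_affected])
    Wi_X = X.copy()
    Wi_y = y.copy()
    logdet_w = 0.0
    for (s, e), nf in zip(fam_slices, fam_sizes):
        shrink = lam / (1.0 + lam * nf)
        Wi_X[s:e] -= shrink * X[s:e].sum(axis=0)
        Wi_y[s:e] -= shrink * y[s:e].sum()
        logdet_w += np.log1p(lam * nf)
    xtwx = X.T @ Wi_X
    xtwy = X.T @ Wi_y
    xtwx_inv = np.linalg.inv(xtwx)
    beta = xtwx_inv @ xtwy
    resid_q = float(y @ Wi_y - beta @ xtwy)  # r' W^-1 r
    p = X.shape[1]
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    crit = logdet_w + logdet_xtwx + (n - p) * np.log(max(resid_q, 1e-300))
    return crit, beta, xtwx_inv, resid_q


def fit_family_lmm(y, sample_meta: pd.DataFrame) -> MixedModelFit:
    """REML fit of the family-random-intercept model for one gene.

    ``y`` is one normalized log-ratio per individual, aligned with
    ``sample_meta`` (columns ``family_id`` and boolean ``affected``).  The
    REML criterion is profiled over the variance ratio with bounded scalar
    optimization; the affection contrast is tested with t = beta/se on
    n_families - 1 containment degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    meta = sample_meta
    fams = list(dict.fromkeys(meta["family_id"]))
    if len(fams) < 2:
        raise ValueError("need at least two families")
    affected = meta["affected"].astype(bool).to_numpy()
    if affected.all() or not affected.any():
        raise ValueError("affection status is constant; the contrast is singular")
    # reorder samples so families are contiguous
    order = np.concatenate(
        [np.flatnonzero(meta["family_id"].to_numpy() == f) for f in fams]
    )
    y = y[order]
    x = affected[order].astype(float)
    fam_sizes = [int((meta["family_id"] == f).sum()) for f in fams]
    fam_slices = []
    pos = 0
    for nf in fam_sizes:
        fam_slices.append((pos, pos + nf))
        pos += nf

    def crit(log_lam):
        return _reml_pieces(y, x, fam_sizes, fam_slices, np.exp(log_lam))[0]

    res = optimize.minimize_scalar(
        crit, bounds=(-30.0, 30.0), method="bounded", options={"xatol": 1e-10}
    )
    lam = float(np.exp(res.x))
    c0 = _reml_pieces(y, x, fam_sizes, fam_slices, 0.0)[0]
    boundary = c0 <= res.fun + 1e-10
    if boundary:
        lam = 0.0
    _, beta, xtwx_inv, resid_q = _reml_pieces(y, x, fam_sizes, fam_slices, lam)
    n, p = y.size, 2
    sigma2_resid = resid_q / (n - p)
    sigma2_family = lam * sigma2_resid
    se = float(np.sqrt(max(sigma2_resid * xtwx_inv[1, 1], 0.0)))
    df = len(fams) - 1
    if se == 0.0:
        t = 0.0
        pval = 1.0
    else:
        t = float(beta[1] / se)
        pval = float(2.0 * stats.t.sf(abs(t), df))
    return MixedModelFit(
        beta_hat=float(beta[1]),
        se_beta=se,
        t_stat=t,
        df=float(df),
        p_value=pval,
        sigma2_family=float(sigma2_family),
        sigma2_resid=float(sigma2_resid),
        mu_hat=float(beta[0]),
        boundary=bool(boundary),
    )


def fit_all_genes(matrix: LogRatioMatrix) -> pd.DataFrame:
    """Fit the mixed model probe by probe; adds the affected-vs-healthy fold change."""
    meta = matrix.sample_meta
    affected_cols = meta.index[meta["affected"].astype(bool)]
    healthy_cols = meta.index[~meta["affected"].astype(bool)]
    rows = []
    for probe, y in matrix.values.iterrows():
        fit = fit_family_lmm(y.to_numpy(), meta)
        fc = float(np.exp(y[affected_cols].mean() - y[healthy_cols].mean()))
        rows.append(
            {
                "probe_id": probe,
                "gene_id": matrix.gene_meta.loc[probe, "gene_id"],
                "band": matrix.gene_meta.loc[probe, "band"],
                "beta_hat": fit.beta_hat,
                "se_beta": fit.se_beta,
                "t_stat": fit.t_stat,
                "df": fit.df,
                "p_value": fit.p_value,
                "sigma2_family": fit.sigma2_family,
                "sigma2_resid": fit.sigma2_resid,
                "fold_change": fc,
            }
        )
    return pd.DataFrame(rows).set_index("probe_id")


def select_de_genes(
    fits: pd.DataFrame,
    alpha: float = 0.025,
    fc_threshold: float | None = None,
    exclusion_list=(),
    location_include=(),
) -> pd.DataFrame:
    """Apply the directional selection rule with optional refinements.

    A gene is selected when its status estimate is positive and p < alpha
    (and, if set, fold change > ``fc_threshold``), unless it appears in the
    stress-response ``exclusion_list``.  Genes in ``location_include`` are
    carried into the call set on genomic position alone (reason
    ``location``), mirroring candidate picks made for locus membership
    rather than expression evidence.
    """
    excluded = {str(g) for g in exclusion_list}
    by_location = {str(g) for g in location_include}
    out = fits.copy()
    selected = []
    reasons = []
    for probe, row in fits.iterrows():
        gene = str(row["gene_id"])
        passes_p = (row["beta_hat"] > 0) and (row["p_value"] < alpha)
        passes_fc = fc_threshold is None or row["fold_change"] > fc_threshold
        if gene in excluded:
            selected.append(False)
            reasons.append("excluded_stress")
        elif passes_p and passes_fc:
            selected.append(True)
            reasons.append("p_only" if fc_threshold is None else "p_and_fc")
        elif gene in by_location:
            selected.append(True)
            reasons.append("location")
        else:
            selected.append(False)
            reasons.append("not_selected")
    out["selected"] = selected
    out["reason"] = reasons
    return out


def run_nmd_de(
    samples,
    band_whitelist=("Xq27", "Xq28"),
    alpha: float = 0.025,
    fc_threshold: float | None = None,
    exclusion_list=(),
    location_include=(),
    floor: float = 1.0,
) -> pd.DataFrame:
    """Full stage: adjust, log-ratio, quantile normalize, region-filter, fit, select."""
    matrix = build_logratio_matrix(samples, floor=floor)
    matrix.values = quantile_normalize(matrix.values)
    matrix = filter_region(matrix, band_whitelist)
    fits = fit_all_genes(matrix)
    return select_de_genes(
        fits,
        alpha=alpha,
        fc_threshold=fc_threshold,
        exclusion_list=exclusion_list,
        location_include=location_include,
    )
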
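"""Per-probe differential methylation on M-values with empirical-Bayes
variance moderation.

For every probe an ordinary least-squares fit of

    M ~ intercept + group + cell proportions (one class dropped)

yields the case/control coefficient on the M scale, the residual variance
s² and its degrees of freedom d.  The per-probe variances are then shrunk
toward a common prior: assuming s² | σ² ~ σ²·χ²_d / d and 1/σ² ~ scaled
χ² with d0 degrees of freedom and scale s0², the posterior variance is

    s̃² = (d0·s0² + d·s²) / (d0 + d),

and the moderated t = coef / (s̃·u) is referred to a t distribution with
d0 + d degrees of freedom (u is the unscaled coefficient standard error
from the design).  d0 and s0² are estimated by moment-matching the log
variances through digamma/trigamma inversion — the standard closed-form
empirical-Bayes recipe for microarray linear models.

Effect sizes for reporting (group means, Δβ) are computed on the beta
scale, where the field quotes methylation differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import CELL_TYPES


class ModelError(ValueError):
    """Bad design matrix or degenerate fit inputs."""


def build_design(
    samples: pd.DataFrame,
    case_ids,
    sample_ids=None,
    use_cell_covariates: bool = True,
) -> pd.DataFrame:
    """Design matrix: intercept, case indicator, and five of the six
    cell-proportion covariates (one dropped — they sum to one)."""
    sheet = samples.set_index("sample_id")
    if sample_ids is None:
        sample_ids = sheet.index.tolist()
    sheet = sheet.loc[list(sample_ids)]
    design = pd.DataFrame(index=sheet.index)
    design["intercept"] = 1.0
    design["group"] = sheet.index.isin(list(case_ids)).astype(float)
    if use_cell_covariates and all(c in sheet.columns for c in CELL_TYPES):
        for ct in CELL_TYPES[:-1]:          # drop the last for identifiability
            design[ct] = sheet[ct].astype(float)
    return design


@dataclass
class ProbeFits:
    """Per-probe OLS results for one coefficient of interest."""

    probe_ids: pd.Index
    coef: np.ndarray            # group coefficient on the M scale
    sigma2: np.ndarray          # residual variance
    df_resid: np.ndarray
    stdev_unscaled: np.ndarray  # sqrt of [(X'X)^-1]_gg per probe


def fit_dmp_model(
    m: pd.DataFrame,
    design: pd.DataFrame,
    coef: str = "group",
) -> ProbeFits:
    """Ordinary least squares per probe; probes with missing entries are
    refit on their observed samples with the degrees of freedom adjusted."""
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        raise ModelError(f"{n} samples cannot identify {p} coefficients")
    if np.linalg.matrix_rank(x) < p:
        raise ModelError("design matrix is rank deficient")
    if list(m.columns) != list(design.index):
        m = m[design.index]
    y = m.to_numpy(dtype=float)
    j = design.columns.get_loc(coef)

    xtx_inv = np.linalg.inv(x.T @ x)
    hat = xtx_inv @ x.T
    complete = ~np.isnan(y).any(axis=1)
    coefs = np.full(y.shape[0], np.nan)
    sigma2 = np.full(y.shape[0], np.nan)
    dfres = np.full(y.shape[0], np.nan)
    unscaled = np.full(y.shape[0], np.nan)

    yc = y[complete]
    b = yc @ hat.T                        # probes x p
    resid = yc - b @ x.T
    coefs[complete] = b[:, j]
    dfres[complete] = n - p
    sigma2[complete] = (resid ** 2).sum(axis=1) / (n - p)
    unscaled[complete] = np.sqrt(xtx_inv[j, j])

    for i in np.where(~complete)[0]:
        obs = ~np.isnan(y[i])
        xo = x[obs]
        if xo.shape[0] <= p or np.linalg.matrix_rank(xo) < p:
            continue                      # left as NaN: unidentifiable probe
        xtx_i = np.linalg.inv(xo.T @ xo)
        bi = xtx_i @ xo.T @ y[i, obs]
        ri = y[i, obs] - xo @ bi
        coefs[i] = bi[j]
        dfres[i] = xo.shape[0] - p
        sigma2[i] = (ri ** 2).sum() / dfres[i]
        unscaled[i] = np.sqrt(xtx_i[j, j])

    return ProbeFits(probe_ids=m.index, coef=coefs, sigma2=sigma2,
                     df_resid=dfres, stdev_unscaled=unscaled)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(
    sigma2: np.ndarray, df_resid: np.ndarray
) -> tuple[float, float]:
    """Moment-match a scaled inverse-χ² prior (df d0, scale s0²) to the
    observed residual variances via the distribution of log s²."""
    ok = np.isfinite(sigma2) & (df_resid > 0)
    s2 = np.clip(sigma2[ok], 1e-300, None)
    if s2.size < 2:
        raise ModelError("need >= 2 finite residual variances")
    if np.all(sigma2[ok] == 0):
        raise ModelError("all residual variances are zero")
    d = df_resid[ok]
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    e_var = np.var(e, ddof=1) - np.mean(special.polygamma(1, d / 2.0))
    if e_var > 0:
        df_prior = 2.0 * _trigamma_inverse(e_var)
        s2_prior = float(np.exp(
            e_mean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)))
    else:
        # degenerate case: no excess spread in log s² beyond sampling noise
        df_prior = np.inf
        s2_prior = float(np.mean(s2))
    return float(df_prior), s2_prior


def moderate_statistics(
    fits: ProbeFits,
    prior_df: float | None = None,
    prior_s2: float | None = None,
) -> pd.DataFrame:
    """Moderated t, two-sided p and BH-adjusted p per probe.

    ``prior_df``/``prior_s2`` override the estimated prior; ``prior_df=0``
    disables shrinkage, reproducing the ordinary t test exactly.
    """
    n_ok = int(np.isfinite(fits.sigma2).sum())
    if n_ok < 10:
        raise ModelError("variance-prior estimation needs >= 10 probes")
    if prior_df is None:
        df_prior, s2_prior = estimate_variance_prior(fits.sigma2,
                                                     fits.df_resid)
    else:
        df_prior = float(prior_df)
        s2_prior = prior_s2 if prior_s2 is not None else float(
            np.nanmean(fits.sigma2))

    d = fits.df_resid
    if np.isinf(df_prior):
        s2_post = np.full_like(fits.sigma2, s2_prior)
    elif df_prior == 0:
        s2_post = fits.sigma2.copy()
    else:
        s2_post = (df_prior * s2_prior + d * fits.sigma2) / (df_prior + d)
    df_total = d + df_prior

    with np.errstate(invalid="ignore", divide="ignore"):
        t = fits.coef / (np.sqrt(s2_post) * fits.stdev_unscaled)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame({
        "probe_id": fits.probe_ids,
        "coef_m": fits.coef,
        "sigma2": fits.sigma2,
        "s2_posterior": s2_post,
        "df_total": df_total,
        "t_moderated": t,
        "p_value": p,
    }).set_index("probe_id")
    finite = np.isfinite(out["p_value"].to_numpy())
    adj = np.full(len(out), np.nan)
    if finite.any():
        adj[finite] = multipletests(out.loc[finite, "p_value"],
                                    method="fdr_bh")[1]
    out["p_adjusted"] = adj
    out.attrs["df_prior"] = df_prior
    out.attrs["s2_prior"] = s2_prior
    return out


def compute_group_means(
    beta: pd.DataFrame, case_ids, control_ids
) -> pd.DataFrame:
    """Arithmetic group means on the beta scale, missing values ignored;
    ``delta_beta`` = case − control."""
    case_ids, control_ids = list(case_ids), list(control_ids)
    if not case_ids or not control_ids:
        raise ValueError("both groups must be non-empty")
    mc = beta[case_ids].mean(axis=1, skipna=True)
    mk = beta[control_ids].mean(axis=1, skipna=True)
    return pd.DataFrame({
        "mean_beta_case": mc,
        "mean_beta_control": mk,
        "delta_beta": mc - mk,
    })


def dmp_statistics(
    beta: pd.DataFrame,
    m: pd.DataFrame,
    samples: pd.DataFrame,
    case_ids,
    control_ids,
    prior_df: float | None = None,
    use_cell_covariates: bool = True,
) -> pd.DataFrame:
    """Full per-probe table: Δβ and group means, moderated t, p, BH p.

    AUC and the probe score are attached downstream by the episignature
    stage, which owns probe selection.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    ids = case_ids + control_ids
    design = build_design(samples, case_ids, sample_ids=ids,
                          use_cell_covariates=use_cell_covariates)
    fits = fit_dmp_model(m[ids], design)
    stats_tbl = moderate_statistics(fits, prior_df=prior_df)
    means = compute_group_means(beta, case_ids, control_ids)
    out = means.join(stats_tbl, how="left")
    out.attrs.update(stats_tbl.attrs)
    return out
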
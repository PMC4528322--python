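"""Per-transcript linear mixed model for reciprocal-cross allelic counts.

For each transcript and sample group the response is ``y = log2(count + 1)``
for every (SNP, library, parental allele) cell, modelled as

    y = b0 + bP*P + bL*L + bPL*(P*L) + u_snp + v_rep + eps

with effect codes P (+1/2 maternal, -1/2 paternal) and L (+1/2 Africanized,
-1/2 European), random intercepts for SNP and for library (replicate), and
Wald chi-square(1) tests per fixed term.  With exactly two reciprocal
families the interaction column P*L is constant within a family (+1/4 in AE,
-1/4 in EA): the interaction is statistically aliased with the family
indicator and is estimated against between-family variation, while the
lineage term is identified by the flip of the parent contrast across
families.  This aliasing is asserted at design-build time.

Variance components are estimated by profiled REML over the nonnegative
orthant; a component estimated at the zero boundary is fixed to zero and the
model refit without it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import chi2

logger = logging.getLogger(__name__)

TERMS = ("parent", "lineage", "interaction")

_EXACT_FIT_RTOL = 1e-10  # residual SS below this fraction of signal => noiseless design
_BOUNDARY_TOL = 1e-6  # variance ratio below this => component at the zero boundary
_REML_TOL = 1e-8  # relative restricted-log-likelihood convergence
_MAX_ITER = 200


@dataclass
class TranscriptFit:
    """Fixed effects, variance components and per-term tests for one transcript."""

    transcript_id: str
    sample_group: str
    coefficients: dict  # intercept, parent, lineage, interaction (NaN if not estimable)
    standard_errors: dict
    sigma2_snp: float
    sigma2_rep: float
    sigma2_resid: float
    p_values: dict  # per TERMS, NaN if not estimable
    converged: bool
    degenerate: bool
    single_family: bool
    n_obs: int
    n_snps: int
    n_replicates: int
    message: str = ""


def build_design(records: pd.DataFrame, response: str = "log2") -> pd.DataFrame:
    """One design row per (SNP, replicate, parent) count cell.

    ``records`` must contain a single transcript and sample group.  Returns
    columns y, P, L, PL, snp_id, replicate_id, family plus an attrs flag
    ``single_family`` when only one family is present (lineage and
    interaction are then inestimable and the fit falls back to parent-only).
    """
    if records["transcript_id"].nunique() > 1 or records["sample_group"].nunique() > 1:
        raise ValueError("build_design expects one transcript and one sample group")
    if response == "log2":
        y = np.log2(records["count"].to_numpy(dtype=float) + 1.0)
    elif response == "raw":
        y = records["count"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown response scale {response!r}")
    P = np.where(records["parent"] == "maternal", 0.5, -0.5)
    L = np.where(records["lineage"] == "Africanized", 0.5, -0.5)
    design = pd.DataFrame(
        {
            "y": y,
            "P": P,
            "L": L,
            "PL": P * L,
            "snp_id": records["chrom"].astype(str) + ":" + records["pos"].astype(str),
            "replicate_id": records["replicate_id"].to_numpy(),
            "family": records["family"].to_numpy(),
        }
    )
    # reciprocal-cross aliasing: within AE, L == P; within EA, L == -P
    fam_sign = np.where(design["family"] == "AE", 0.25, -0.25)
    assert np.allclose(design["PL"], fam_sign), "PL column must equal the scaled family indicator"
    design.attrs["single_family"] = records["family"].nunique() < 2
    if design.attrs["single_family"]:
        logger.warning(
            "transcript %s (%s): counts from a single family; lineage and interaction "
            "terms are not estimable, fitting parent-only model",
            records["transcript_id"].iloc[0],
            records["sample_group"].iloc[0],
        )
    return design


def _indicator(labels: np.ndarray) -> np.ndarray:
    levels, inv = np.unique(labels, return_inverse=True)
    Z = np.zeros((labels.shape[0], levels.shape[0]))
    Z[np.arange(labels.shape[0]), inv] = 1.0
    return Z


def _neg2_restricted_ll(gammas, ZZts, X, y):
    n, p = X.shape
    W = np.eye(n)
    for g, ZZt in zip(gammas, ZZts):
        W += g * ZZt
    try:
        c, low = linalg.cho_factor(W, lower=True)
    except linalg.LinAlgError:
        return np.inf, None
    logdet_W = 2.0 * np.sum(np.log(np.diag(c)))
    Wi_X = linalg.cho_solve((c, low), X)
    Wi_y = linalg.cho_solve((c, low), y)
    XtWiX = X.T @ Wi_X
    try:
        beta = linalg.solve(XtWiX, X.T @ Wi_y, assume_a="pos")
    except linalg.LinAlgError:
        return np.inf, None
    r = y - X @ beta
    rss = float(r @ linalg.cho_solve((c, low), r))
    if rss <= 0:
        return np.inf, None
    sign, logdet_XtWiX = np.linalg.slogdet(XtWiX)
    if sign <= 0:
        return np.inf, None
    crit = logdet_W + logdet_XtWiX + (n - p) * np.log(rss)
    return crit, (beta, XtWiX, rss, c, low)


def _gls_summary(gammas, ZZts, X, y):
    crit, aux = _neg2_restricted_ll(gammas, ZZts, X, y)
    if aux is None:
        raise RuntimeError("GLS evaluation failed at the REML optimum")
    beta, XtWiX, rss, _, _ = aux
    n, p = X.shape
    sigma2_e = rss / (n - p)
    cov_beta = sigma2_e * linalg.inv(XtWiX)
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    return beta, se, sigma2_e


def wald_term_test(beta: float, se: float) -> float:
    """Upper chi-square(1) tail of (beta/se)^2.

    With a degenerate zero standard error the convention is p=1 for a zero
    coefficient and p=0 for a nonzero one (infinite statistic); such fits are
    flagged non-standard by the caller.
    """
    if np.isnan(beta) or np.isnan(se):
        return np.nan
    if se == 0.0:
        return 1.0 if abs(beta) < 1e-8 else 0.0
    return float(chi2.sf((beta / se) ** 2, 1))


def fit_mixed_model(design: pd.DataFrame, transcript_id: str = "", sample_group: str = "") -> TranscriptFit:
    """REML fit of the parent/lineage/interaction mixed model for one design.

    Requires at least two distinct parent codes and four rows.  Random
    intercepts with a single level are inestimable (confounded with the
    intercept) and are omitted; variance components at the zero boundary are
    set to zero with a single refit.  Noiseless designs (exact interpolation)
    short-circuit to the OLS solution with all variance components zero and
    the degenerate p-value convention of :func:`wald_term_test`.
    """
    n = len(design)
    if design["P"].nunique() < 2:
        raise ValueError("design must contain both maternal and paternal rows")
    if n < 4:
        raise ValueError(f"need >= 4 rows to fit the mixed model, got {n}")
    y = design["y"].to_numpy(dtype=float)
    single_family = bool(design.attrs.get("single_family", design["family"].nunique() < 2))
    if single_family:
        X = np.column_stack([np.ones(n), design["P"].to_numpy()])
        fixed_names = ["intercept", "parent"]
    else:
        X = np.column_stack(
            [np.ones(n), design["P"].to_numpy(), design["L"].to_numpy(), design["PL"].to_numpy()]
        )
        fixed_names = ["intercept", "parent", "lineage", "interaction"]
    p = X.shape[1]

    rand_names, ZZts = [], []
    n_snps = design["snp_id"].nunique()
    n_reps = design["replicate_id"].nunique()
    for name, labels, levels in [
        ("snp", design["snp_id"].to_numpy(), n_snps),
        ("rep", design["replicate_id"].to_numpy(), n_reps),
    ]:
        if levels >= 2:
            Z = _indicator(labels)
            rand_names.append(name)
            ZZts.append(Z @ Z.T)

    beta_ols, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss_ols = float(np.sum((y - X @ beta_ols) ** 2))
    scale = max(float(np.sum(y**2)), 1.0)

    sigma2 = {"snp": 0.0, "rep": 0.0}
    degenerate = False
    converged = True
    message = ""

    if rank < p:
        raise ValueError("singular fixed-effect design")

    if rss_ols <= _EXACT_FIT_RTOL * scale or n - p <= 0:
        # exact interpolation (or saturated design): no residual information
        degenerate = True
        beta, se, sigma2_e = beta_ols, np.zeros(p), 0.0
        message = "degenerate: zero residual variance"
    else:
        active = list(range(len(ZZts)))
        while True:
            if not active:
                beta, se, sigma2_e = _gls_summary([], [], X, y)
                gammas_hat = []
                break
            sub = [ZZts[i] for i in active]
            res = optimize.minimize(
                lambda g: _neg2_restricted_ll(g, sub, X, y)[0],
                x0=np.full(len(sub), 0.5),
                method="L-BFGS-B",
                bounds=[(0.0, 1e8)] * len(sub),
                options={"ftol": _REML_TOL, "maxiter": _MAX_ITER},
            )
            converged = bool(res.success)
            if not converged:
                message = f"REML optimizer: {res.message}"
            gammas_hat = res.x
            at_boundary = [i for i, g in enumerate(gammas_hat) if g < _BOUNDARY_TOL]
            if at_boundary:
                # truncate boundary components to zero and refit without them
                active = [a for j, a in enumerate(active) if j not in at_boundary]
                if not active:
                    beta, se, sigma2_e = _gls_summary([], [], X, y)
                    gammas_hat = []
                    break
                continue
            beta, se, sigma2_e = _gls_summary(gammas_hat, sub, X, y)
            break
        for name_i, g in zip([rand_names[i] for i in active], gammas_hat):
            sigma2[name_i] = float(g) * sigma2_e

    coef = dict.fromkeys(["intercept", "parent", "lineage", "interaction"], np.nan)
    ses = dict.fromkeys(["intercept", "parent", "lineage", "interaction"], np.nan)
    for name, b, s in zip(fixed_names, beta, se):
        coef[name], ses[name] = float(b), float(s)
    pvals = {t: wald_term_test(coef[t], ses[t]) for t in TERMS}
    return TranscriptFit(
        transcript_id=transcript_id,
        sample_group=sample_group,
        coefficients=coef,
        standard_errors=ses,
        sigma2_snp=sigma2["snp"],
        sigma2_rep=sigma2["rep"],
        sigma2_resid=float(sigma2_e),
        p_values=pvals,
        converged=converged,
        degenerate=degenerate,
        single_family=single_family,
        n_obs=n,
        n_snps=n_snps,
        n_replicates=n_reps,
        message=message,
    )


def fit_to_row(fit: TranscriptFit) -> dict:
    row = {
        "transcript_id": fit.transcript_id,
        "sample_group": fit.sample_group,
        "n_obs": fit.n_obs,
        "n_snps": fit.n_snps,
        "n_replicates": fit.n_replicates,
        "sigma2_snp": fit.sigma2_snp,
        "sigma2_rep": fit.sigma2_rep,
        "sigma2_resid": fit.sigma2_resid,
        "converged": fit.converged,
        "degenerate": fit.degenerate,
        "single_family": fit.single_family,
    }
    for name in ["intercept", "parent", "lineage", "interaction"]:
        row[f"beta_{name}"] = fit.coefficients[name]
        row[f"se_{name}"] = fit.standard_errors[name]
    for t in TERMS:
        row[f"p_{t}"] = fit.p_values[t]
    return row


def fit_all(counts: pd.DataFrame, response: str = "log2") -> pd.DataFrame:
    """Fit every (transcript, sample group) in a filtered counts table.

    Transcripts whose counts are all zero are excluded with a logged reason;
    single-family transcripts fall back to the parent-only model.
    """
    rows = []
    for (tid, group), sub in counts.groupby(["transcript_id", "sample_group"], sort=True):
        if sub["count"].sum() == 0:
            logger.info("transcript %s (%s): all counts zero, untestable", tid, group)
            continue
        design = build_design(sub, response=response)
        try:
            fit = fit_mixed_model(design, transcript_id=str(tid), sample_group=str(group))
        except ValueError as exc:
            logger.info("transcript %s (%s): %s; skipped", tid, group, exc)
            continue
        rows.append(fit_to_row(fit))
    cols = list(fit_to_row(_dummy_fit()).keys())
    return pd.DataFrame(rows, columns=cols)


def _dummy_fit() -> TranscriptFit:
    nan4 = dict.fromkeys(["intercept", "parent", "lineage", "interaction"], np.nan)
    return TranscriptFit(
        transcript_id="",
        sample_group="",
        coefficients=dict(nan4),
        standard_errors=dict(nan4),
        sigma2_snp=0.0,
        sigma2_rep=0.0,
        sigma2_resid=0.0,
        p_values=dict.fromkeys(TERMS, np.nan),
        converged=True,
        degenerate=False,
        single_family=False,
        n_obs=0,
        n_snps=0,
        n_replicates=0,
    )


def fdr_adjust(fits: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up q-values within each sample group x term.

    Adds ``q_parent``, ``q_lineage``, ``q_interaction`` columns; NaN p-values
    (inestimable terms) are left out of the adjustment and stay NaN.
    """
    from statsmodels.stats.multitest import multipletests

    out = fits.copy()
    for t in TERMS:
        out[f"q_{t}"] = np.nan
    if len(out) == 0:
        return out
    for group, idx in out.groupby("sample_group").groups.items():
        for t in TERMS:
            p = out.loc[idx, f"p_{t}"]
            mask = p.notna()
            if mask.sum() == 0:
                continue
            _, q, _, _ = multipletests(p[mask].to_numpy(), alpha=q_threshold, method="fdr_bh")
            out.loc[p.index[mask], f"q_{t}"] = q
    return out
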
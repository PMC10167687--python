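"""Assembled mass fraction (AMF) analysis and its differential test.

The AMF of a protein in one sample is the share of its total detected SEC
signal that elutes in the assembled mass range, i.e. in fractions earlier
than the fraction corresponding to twice the protein's monomeric molecular
weight (2xMMW).  Because AMF values are proportions bounded by 0 and 1 and
not normally distributed, differences across conditions are tested with a
beta regression (logit mean link, constant precision) and a likelihood
ratio test, after shrinking the observed proportions away from the {0, 1}
extremes.  Multiple testing is corrected by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("secdiff")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class BetaRegressionFit:
    """Maximum-likelihood beta regression fit (logit mean link)."""

    coef: np.ndarray          # mean-model coefficients on the logit scale
    phi: float                # precision parameter (> 0)
    loglik: float
    converged: bool = True

    @property
    def fitted_means(self):
        return None  # filled by caller when the design is known


@dataclass
class MassFractionResult:
    """Per-protein mass-fraction (AMF or FMF) differential result."""

    protein_id: str
    values: dict                      # sample_id -> y in [0, 1]
    mean_a: float = float("nan")
    mean_b: float = float("nan")
    diff: float = float("nan")        # mean_a - mean_b
    p_value: float = float("nan")
    adjusted_p: float = float("nan")
    significant: bool = False
    direction: str = ""               # "increase" / "decrease" / ""
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Assembled / monomeric split
# ---------------------------------------------------------------------------

def assembled_cutoff_fraction(monomeric_mw, calibration, max_fraction):
    """Fraction splitting the assembled from the monomeric SEC range.

    The cutoff sits at the fraction where a particle of twice the protein's
    monomeric molecular weight elutes; fractions strictly below it
    (earlier-eluting, higher apparent MW) form the assembled range.  The
    returned value is clamped into ``[1, max_fraction]`` and may be
    fractional.
    """
    if monomeric_mw is None or not monomeric_mw > 0:
        raise ValueError("protein requires a positive monomeric MW annotation")
    cutoff = float(calibration.mw_to_fraction(2.0 * monomeric_mw))
    return float(np.clip(cutoff, 1.0, max_fraction))


def compute_amf(trace, cutoff):
    """Assembled mass fraction of one per-sample protein trace.

    ``y = (signal in fractions strictly below cutoff) / (total signal)``;
    all fractions contribute — no peak extraction is involved.  Returns NaN
    when the trace holds no signal (the sample is then excluded from the
    differential test).
    """
    y = np.nan_to_num(np.asarray(trace, dtype=float), nan=0.0)
    total = y.sum()
    if total <= 0:
        return float("nan")
    fractions = np.arange(1, len(y) + 1)
    return float(y[fractions < cutoff].sum() / total)


def transform_unit_interval(y, n):
    """Shrink proportions from [0, 1] into the open interval (0, 1).

    ``y' = (y * (n - 1) + 0.5) / n`` with ``n`` the sample size; the affine
    map is order-preserving and sends [0, 1] onto [0.5/n, 1 - 0.5/n],
    making boundary observations usable by the beta likelihood.
    """
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must lie in [0, 1]")
    return (y * (n - 1) + 0.5) / n


# ---------------------------------------------------------------------------
# Beta regression likelihood-ratio test
# ---------------------------------------------------------------------------

_LOGPHI_MAX = 25.0  # caps the precision so degenerate fits stay finite


def _beta_negll_grad(params, X, y):
    """Negative log-likelihood and gradient of logit-link beta regression.

    Parameterization: mean mu = sigmoid(X beta), precision phi = exp(theta),
    y ~ Beta(mu*phi, (1-mu)*phi).
    """
    beta, theta = params[:-1], params[-1]
    phi = np.exp(theta)
    eta = X @ beta
    mu = special.expit(eta)
    a = mu * phi
    b = (1.0 - mu) * phi
    ly, l1y = np.log(y), np.log1p(-y)
    ll = np.sum(special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
                + (a - 1.0) * ly + (b - 1.0) * l1y)
    dmu = phi * (-special.digamma(a) + special.digamma(b) + ly - l1y)
    gbeta = X.T @ (dmu * mu * (1.0 - mu))
    dphi = np.sum(special.digamma(phi) - mu * special.digamma(a)
                  - (1.0 - mu) * special.digamma(b) + mu * ly + (1.0 - mu) * l1y)
    gtheta = phi * dphi
    return -ll, -np.concatenate([gbeta, [gtheta]])


def fit_beta_regression(y, X):
    """Fit a beta regression by maximum likelihood (L-BFGS-B).

    ``X`` is the mean-model design matrix (first column the intercept);
    the precision is constant across observations.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    # starting values: OLS on the logit scale, method-of-moments precision
    z = special.logit(np.clip(y, 1e-6, 1 - 1e-6))
    beta0, *_ = np.linalg.lstsq(X, z, rcond=None)
    mu0 = special.expit(X @ beta0)
    resid_var = max(np.var(y - mu0, ddof=0), 1e-10)
    mbar = float(np.mean(mu0))
    phi0 = np.clip(mbar * (1 - mbar) / resid_var - 1.0, 1.0, 1e6)
    x0 = np.concatenate([beta0, [np.log(phi0)]])
    bounds = [(None, None)] * X.shape[1] + [(-5.0, _LOGPHI_MAX)]
    res = optimize.minimize(
        _beta_negll_grad, x0, args=(X, y), jac=True, method="L-BFGS-B",
        bounds=bounds, options={"maxiter": 200},
    )
    return BetaRegressionFit(
        coef=res.x[:-1], phi=float(np.exp(res.x[-1])),
        loglik=float(-res.fun), converged=bool(res.success),
    )


def beta_lrt(y_prime, groups):
    """Likelihood-ratio test for a mean difference between two groups.

    Fits the full model (mean ~ group, logit link, constant precision) and
    the intercept-only null by maximum likelihood; the p-value is the upper
    chi-square tail (df = number of groups - 1) at twice the log-likelihood
    gain.  Degenerate inputs (all values equal) and non-convergent fits
    report p = 1.
    """
    y = np.asarray(y_prime, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need >=2 groups")
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise ValueError(f"group {lev!r} has <2 usable samples")
    if np.allclose(y, y[0]):
        return 1.0
    n = len(y)
    X_full = np.column_stack(
        [np.ones(n)] + [(groups == lev).astype(float) for lev in levels[1:]]
    )
    X_null = np.ones((n, 1))
    full = fit_beta_regression(y, X_full)
    null = fit_beta_regression(y, X_null)
    if not (full.converged and null.converged):
        logger.debug("beta regression non-convergence; reporting p=1")
        return 1.0
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    df = len(levels) - 1
    return float(stats.chi2.sf(stat, df))


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Differential AMF analysis
# ---------------------------------------------------------------------------

def amf_per_sample(protein_traces, mw_annotation, calibration):
    """Per-sample AMF values for every annotated protein.

    Returns a DataFrame (protein x sample) of AMF values plus a dict of
    cutoff fractions; proteins without MW annotation are excluded (logged).
    """
    rows = {}
    cutoffs = {}
    for prot in protein_traces.protein_ids:
        mmw = mw_annotation.get(prot)
        if mmw is None:
            logger.info("protein %s lacks MW annotation; excluded from AMF", prot)
            continue
        cutoff = assembled_cutoff_fraction(mmw, calibration, protein_traces.n_fractions)
        cutoffs[prot] = cutoff
        k = protein_traces.protein_index(prot)
        rows[prot] = {
            s: compute_amf(protein_traces.data[k, si], cutoff)
            for si, s in enumerate(protein_traces.sample_ids)
        }
    frame = pd.DataFrame(rows).T
    if len(frame):
        frame = frame.reindex(columns=protein_traces.sample_ids)
    return frame, cutoffs


def mass_fraction_differential(values, design, condition_a, condition_b,
                               min_diff=0.3, alpha=0.05):
    """Differential test of bounded mass fractions (AMF or FMF) per protein.

    ``values`` is a protein x sample DataFrame of proportions in [0, 1].
    For each protein, the difference of condition means (A - B) is paired
    with a beta-regression LRT p-value on extreme-shrunk values; BH
    adjustment runs across proteins, and significance requires
    ``|diff| >= min_diff`` and ``adjusted_p <= alpha``.
    """
    samp_a = design.samples_for(condition_a)
    samp_b = design.samples_for(condition_b)
    n_total = len(samp_a) + len(samp_b)
    results = []
    for prot, row in values.iterrows():
        ya = row[samp_a].to_numpy(dtype=float)
        yb = row[samp_b].to_numpy(dtype=float)
        ya, yb = ya[np.isfinite(ya)], yb[np.isfinite(yb)]
        res = MassFractionResult(
            protein_id=prot,
            values={s: row[s] for s in samp_a + samp_b if np.isfinite(row[s])},
        )
        if len(ya) < 2 or len(yb) < 2:
            res.flags.append("insufficient_samples")
            logger.info("protein %s: <2 usable samples in a condition; skipped", prot)
            results.append(res)
            continue
        res.mean_a = float(ya.mean())
        res.mean_b = float(yb.mean())
        res.diff = res.mean_a - res.mean_b
        y = transform_unit_interval(np.concatenate([ya, yb]), n_total)
        groups = np.array(["A"] * len(ya) + ["B"] * len(yb))
        res.p_value = beta_lrt(y, groups)
        results.append(res)
    tested = [r for r in results if np.isfinite(r.p_value)]
    if tested:
        adj = bh_adjust([r.p_value for r in tested])
        for r, a in zip(tested, adj):
            r.adjusted_p = float(a)
            r.significant = abs(r.diff) >= min_diff and r.adjusted_p <= alpha
            if r.significant:
                r.direction = "increase" if r.diff > 0 else "decrease"
    return results


def amf_differential(protein_traces, mw_annotation, calibration, design,
                     condition_a, condition_b, min_diff=0.3, alpha=0.05):
    """End-to-end AMF differential analysis between two conditions."""
    values, _ = amf_per_sample(protein_traces, mw_annotation, calibration)
    values = values[design.samples_for(condition_a) + design.samples_for(condition_b)]
    return mass_fraction_differential(
        values, design, condition_a, condition_b, min_diff=min_diff, alpha=alpha
    )


def mass_fraction_frame(results):
    """Tabular view of mass-fraction differential results."""
    return pd.DataFrame([
        {
            "protein_id": r.protein_id, "mean_a": r.mean_a, "mean_b": r.mean_b,
            "diff": r.diff, "p_value": r.p_value, "adjusted_p": r.adjusted_p,
            "significant": r.significant, "direction": r.direction,
            "flags": ";".join(r.flags),
        }
        for r in results
    ])
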
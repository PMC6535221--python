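"""Negative-binomial differential expression between two groups within a phase.

The classic exact conditional NB test: per-sample library scale is estimated
by the median-of-ratios size factors; per-feature overdispersion alpha (with
variance mu + alpha*mu^2) by a pooled method-of-moments estimator on
normalized counts; the test then conditions on the total count of a feature
across both groups and asks how extreme the observed split between groups is
under NB laws for the two group sums.  Fold changes are ratios of mean
normalized counts (group B over group A); BH adjustment is applied across the
features in one call, and the final call uses the symmetric rule
FC > threshold (up) or FC < 1/threshold (down) with p < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, EstimationError
from .models import SampleSheet

DISPERSION_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# size factors and dispersion
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over features i (restricted to features positive in every
    sample) of k_ij / geometric_mean_i.
    """
    x = counts.values.astype(float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise EstimationError(
            "no feature has nonzero counts in every sample; size factors are "
            "undefined — filter samples or supply size factors explicitly"
        )
    logs = np.log(x[positive])
    loggeo = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - loggeo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    return counts.div(sf, axis=1)


def _mom_dispersion_raw(counts: pd.DataFrame, sf: pd.Series,
                        conditions: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Unfloored method-of-moments dispersion and pooled normalized mean.

    On normalized counts z = k/s: alpha_i = (v_i - mu_i * mean(1/s)) / mu_i^2,
    where v_i pools the within-condition sample variances and the
    mu_i*mean(1/s) term removes the counting (shot) noise.
    """
    conditions = conditions.reindex(counts.columns)
    levels = conditions.unique()
    sizes = conditions.value_counts()
    if (sizes < 2).any():
        raise EstimationError(
            f"dispersion estimation needs >=2 replicates per condition; got "
            f"{sizes.to_dict()}"
        )
    z = normalized_counts(counts, sf)
    num = np.zeros(len(counts))
    df_total = 0
    for lev in levels:
        cols = conditions.index[conditions == lev]
        sub = z[cols].values
        num += sub.var(axis=1, ddof=1) * (len(cols) - 1)
        df_total += len(cols) - 1
    v = num / df_total
    mu = z.values.mean(axis=1)
    shot = mu * float((1.0 / sf).mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - shot) / mu**2
    alpha = np.where(mu > 0, alpha, 0.0)
    return alpha, mu


def estimate_dispersion(counts: pd.DataFrame, sf: pd.Series,
                        conditions: pd.Series,
                        floor: float = DISPERSION_FLOOR) -> pd.Series:
    """Per-feature method-of-moments dispersion, pooled over conditions and
    floored at *floor*.  Unbiased for the true alpha as replication grows,
    but very noisy at n = 3 per group; see :func:`shared_dispersions`."""
    alpha, _ = _mom_dispersion_raw(counts, sf, conditions)
    alpha = np.maximum(alpha, floor)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def dispersion_trend(mu: np.ndarray, raw_alpha: np.ndarray) -> np.ndarray:
    """Parametric mean-dispersion trend alpha(mu) = a0 + a1/mu, fit over
    features with a positive raw estimate and evaluated at every mu.

    The fit is a trimmed least squares: after each pass, features whose raw
    estimate sits more than 3 robust SDs (MAD) above the fitted curve are
    dropped and the curve refit, so a handful of genuinely hyper-variable
    features cannot drag the trend up for everything else.
    """
    use = (raw_alpha > 0) & (mu > 0) & np.isfinite(raw_alpha)
    if use.sum() < 2:
        return np.zeros_like(mu)
    sel = np.nonzero(use)[0]
    coef = np.zeros(2)
    for _ in range(4):
        X = np.column_stack([np.ones(len(sel)), 1.0 / mu[sel]])
        coef, *_ = np.linalg.lstsq(X, raw_alpha[sel], rcond=None)
        resid = raw_alpha[sel] - X @ coef
        mad = np.median(np.abs(resid - np.median(resid)))
        if mad == 0:
            break
        keep = resid <= 3.0 * 1.4826 * mad
        if keep.all() or keep.sum() < 2:
            break
        sel = sel[keep]
    with np.errstate(divide="ignore"):
        fitted = coef[0] + coef[1] / mu
    return np.where(mu > 0, np.maximum(fitted, 0.0), 0.0)


def shared_dispersions(counts: pd.DataFrame, sf: pd.Series,
                       conditions: pd.Series,
                       floor: float = DISPERSION_FLOOR) -> pd.Series:
    """Conservative dispersion for small replicate numbers: the per-feature
    maximum of the pooled MoM estimate and the fitted mean-dispersion trend.

    With 3 replicates per group the per-feature MoM estimate is often zero by
    chance, which makes the exact test anti-conservative; taking the maximum
    against the cross-feature trend restores type-I control while keeping any
    feature-specific extra-Poisson variability.
    """
    raw, mu = _mom_dispersion_raw(counts, sf, conditions)
    fitted = dispersion_trend(mu, raw)
    alpha = np.maximum(np.maximum(raw, fitted), floor)
    return pd.Series(alpha, index=counts.index, name="dispersion")


@dataclass
class NBModel:
    """Fitted nuisance parameters for one two-group comparison."""

    size_factors: pd.Series
    dispersions: pd.Series
    samples_a: list[str]
    samples_b: list[str]


def fit_nb_model(counts: pd.DataFrame, sheet: SampleSheet, phase: str,
                 group_a: str = "monotocous", group_b: str = "polytocous",
                 sharing: str = "maximum") -> NBModel:
    """Estimate size factors and dispersions for the two groups of one phase.

    *sharing*: ``maximum`` (default; max of per-feature MoM and the fitted
    mean-dispersion trend) or ``per_gene`` (raw MoM only).
    """
    samples_a = sheet.select(group=group_a, phase=phase)
    samples_b = sheet.select(group=group_b, phase=phase)
    sub = counts[samples_a + samples_b]
    sf = size_factors(sub)
    cond = pd.Series(["A"] * len(samples_a) + ["B"] * len(samples_b),
                     index=samples_a + samples_b)
    if sharing == "maximum":
        disp = shared_dispersions(sub, sf, cond)
    elif sharing == "per_gene":
        disp = estimate_dispersion(sub, sf, cond)
    else:
        raise ConfigurationError("sharing must be 'maximum' or 'per_gene'")
    return NBModel(sf, disp, samples_a, samples_b)


# ---------------------------------------------------------------------------
# exact conditional test
# ---------------------------------------------------------------------------

def _nb_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """NB log-pmf parameterized by mean and variance (Poisson when var<=mean)."""
    if var <= mean * (1.0 + 1e-12):
        return stats.poisson.logpmf(k, mean)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def exact_nb_pvalue(k_a: int, k_b: int, mean_a: float, mean_b: float,
                    var_a: float, var_b: float) -> float:
    """Two-sided conditional exact p: the probability, given the total
    k_a + k_b, of any split as or less likely than the observed one."""
    total = int(k_a) + int(k_b)
    if total == 0 or mean_a <= 0 or mean_b <= 0:
        return 1.0
    a = np.arange(total + 1)
    logp = _nb_logpmf(a, mean_a, var_a) + _nb_logpmf(total - a, mean_b, var_b)
    log_obs = logp[int(k_a)]
    m = logp.max()
    w = np.exp(logp - m)
    keep = logp <= log_obs + 1e-7
    denom = w.sum()
    if denom <= 0 or not np.isfinite(denom):
        return 1.0
    return float(min(1.0, w[keep].sum() / denom))


def nb_test(counts: pd.DataFrame, model: NBModel) -> pd.DataFrame:
    """Per-feature exact conditional NB test (group B vs group A).

    Returns a frame with baseMean_A/B (mean normalized counts), fold_change
    (B/A), log2fc, pvalue, padj (BH across this frame's features) and a flag
    for degenerate fold changes.
    """
    sa, sb = model.samples_a, model.samples_b
    sf = model.size_factors
    sub = counts[sa + sb]
    z = normalized_counts(sub, sf)
    q_hat = z.mean(axis=1)  # pooled mean under the null

    sfa = sf[sa].values
    sfb = sf[sb].values
    S_a, S_b = sfa.sum(), sfb.sum()
    SS_a, SS_b = (sfa**2).sum(), (sfb**2).sum()

    ka = sub[sa].sum(axis=1).values
    kb = sub[sb].sum(axis=1).values
    base_a = z[sa].mean(axis=1).values
    base_b = z[sb].mean(axis=1).values
    alpha = model.dispersions.reindex(counts.index).values
    q = q_hat.values

    n = len(counts)
    pvals = np.ones(n)
    fc = np.ones(n)
    flags = np.array([""] * n, dtype=object)
    for i in range(n):
        mean_a = q[i] * S_a
        mean_b = q[i] * S_b
        var_a = mean_a + alpha[i] * q[i] ** 2 * SS_a
        var_b = mean_b + alpha[i] * q[i] ** 2 * SS_b
        pvals[i] = exact_nb_pvalue(ka[i], kb[i], mean_a, mean_b, var_a, var_b)
        if base_a[i] == 0 and base_b[i] == 0:
            fc[i] = 1.0
            flags[i] = "all_zero"
        elif base_a[i] == 0:
            fc[i] = np.inf
            flags[i] = "zero_in_A"
        else:
            fc[i] = base_b[i] / base_a[i]
            if base_b[i] == 0:
                flags[i] = "zero_in_B"

    with np.errstate(divide="ignore"):
        log2fc = np.log2(fc)
    padj = multipletests(pvals, method="fdr_bh")[1] if n else np.array([])
    return pd.DataFrame({
        "feature_id": counts.index,
        "baseMean_A": base_a,
        "baseMean_B": base_b,
        "fold_change": fc,
        "log2fc": log2fc,
        "pvalue": pvals,
        "padj": padj,
        "flag": flags,
    }).set_index("feature_id")


def call_de(records: pd.DataFrame, fc_threshold: float = 1.5,
            alpha: float = 0.05, use: str = "pvalue") -> pd.DataFrame:
    """Apply the symmetric call rule: up iff FC > threshold, down iff
    FC < 1/threshold, each requiring p (or padj with ``use='padj'``) < alpha."""
    if use not in ("pvalue", "padj"):
        raise ConfigurationError("use must be 'pvalue' or 'padj'")
    p = records[use]
    fc = records["fold_change"]
    call = np.where((fc > fc_threshold) & (p < alpha), "up",
                    np.where((fc < 1.0 / fc_threshold) & (p < alpha), "down", "ns"))
    out = records.copy()
    out["call"] = call
    return out


def de_analysis(counts: pd.DataFrame, sheet: SampleSheet, phase: str,
                group_a: str = "monotocous", group_b: str = "polytocous",
                fc_threshold: float = 1.5, alpha: float = 0.05,
                use: str = "pvalue") -> pd.DataFrame:
    """Fit the NB model on one phase's samples and return called DE records."""
    model = fit_nb_model(counts, sheet, phase, group_a, group_b)
    records = nb_test(counts, model)
    return call_de(records, fc_threshold=fc_threshold, alpha=alpha, use=use)
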
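"""Causal-effect estimators for two-sample MR on a harmonized table.

Each SNP provides a Wald ratio Γ/γ (SNP-outcome over SNP-exposure effect);
the estimators combine these under different assumptions about pleiotropy:

* ``ivw`` — inverse-variance-weighted meta-analysis, equivalently weighted
  regression of Γ on γ through the origin; the primary analysis. The default
  multiplicative random-effects model inflates the fixed-effect SE by
  √(Q/(J−1)) when the instruments are over-dispersed (never deflates).
* ``mr_egger`` — the same regression with an unconstrained intercept; the
  intercept estimates directional pleiotropy and the slope remains consistent
  under the InSIDE assumption.
* ``weighted_median`` — median of the inverse-variance-weighted empirical
  distribution of ratios; consistent when ≥ 50% of weight is on valid
  instruments.
* ``weighted_mode`` / ``simple_mode`` — kernel-smoothed mode of the ratio
  distribution (inverse-variance or equal weights); consistent when the
  largest homogeneous cluster of instruments is valid (ZEMPA).

Median and mode standard errors come from a seeded parametric bootstrap. For
binary outcomes betas are log odds ratios, so ``exp(beta)`` is the OR reported
alongside a 95% Wald interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .sumstats import HarmonizedTable, InputError

logger = logging.getLogger(__name__)

Z95 = 1.96  #: normal quantile used for all 95% Wald intervals

METHODS = ("ivw", "egger", "weighted_median", "weighted_mode", "simple_mode")
#: fewest SNPs each estimator is defined for (single-SNP IVW = the Wald ratio)
MIN_SNPS = {"ivw": 1, "egger": 3, "weighted_median": 3, "weighted_mode": 3, "simple_mode": 3}


@dataclass
class MREstimate:
    """One estimator's causal-effect estimate on the log-odds (or SD) scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z95 * self.se))


def _arrays(h: HarmonizedTable):
    df = h.df
    return (
        df["gamma"].to_numpy(float),
        df["se_gamma"].to_numpy(float),
        df["Gamma"].to_numpy(float),
        df["se_Gamma"].to_numpy(float),
    )


def _norm_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratios(h: HarmonizedTable) -> pd.DataFrame:
    """Per-SNP causal estimates: ratio = Γ/γ, first-order delta SE = se_Γ/|γ|.

    Rows with γ = 0 (undefined ratio) are dropped with a warning.
    """
    if len(h) == 0:
        raise InputError("empty harmonized table")
    g, _, G, seG = _arrays(h)
    nonzero = g != 0
    if not nonzero.all():
        logger.warning("dropping %d SNP(s) with zero exposure effect", int((~nonzero).sum()))
    return pd.DataFrame(
        {
            "snp": h.df.loc[nonzero, "snp"].to_numpy(),
            "ratio": G[nonzero] / g[nonzero],
            "se_ratio": seG[nonzero] / np.abs(g[nonzero]),
        }
    )


def ivw(h: HarmonizedTable, model: str = "random_multiplicative") -> MREstimate:
    """Inverse-variance-weighted estimate.

    beta = Σ(γΓ/se_Γ²) / Σ(γ²/se_Γ²); fixed-effect SE = (Σγ²/se_Γ²)^(−1/2);
    the multiplicative random-effects model (default) scales the SE by
    max(1, √(Q/(J−1))).
    """
    if len(h) == 0:
        raise InputError("IVW requires at least one SNP")
    if model not in ("fixed", "random_multiplicative"):
        raise ValueError(f"unknown IVW model {model!r}")
    g, _, G, seG = _arrays(h)
    w = 1.0 / seG**2
    denom = float(np.sum(g**2 * w))
    beta = float(np.sum(g * G * w) / denom)
    se = denom**-0.5
    J = len(g)
    if model == "random_multiplicative" and J > 1:
        q = float(np.sum(w * (G - beta * g) ** 2))
        se *= max(1.0, np.sqrt(q / (J - 1)))
    return MREstimate("ivw", beta, se, _norm_p(beta / se), J)


def mr_egger(h: HarmonizedTable, p_dist: str = "normal") -> MREstimate | None:
    """MR-Egger regression: weighted regression of Γ on γ with an intercept.

    γ is re-oriented positive (flipping Γ with it) before fitting, so the
    intercept captures directional pleiotropy irrespective of the arbitrary
    effect-allele orientation. SEs carry a multiplicative over-dispersion
    factor max(1, residual scale). ``p_dist`` selects two-sided normal
    (default, consistent with the other estimators) or t with J−2 df.

    Returns ``None`` below 3 SNPs (method inapplicable, not an error).
    """
    J = len(h)
    if J < MIN_SNPS["egger"]:
        logger.warning("MR-Egger inapplicable with %d SNP(s); needs >= 3", J)
        return None
    g, _, G, seG = _arrays(h)
    sign = np.where(g < 0, -1.0, 1.0)
    g, G = g * sign, G * sign
    w = 1.0 / seG**2
    fit = sm.WLS(G, sm.add_constant(g), weights=w).fit()
    inflate = np.sqrt(max(1.0, float(fit.scale)))
    se_int, se_slope = np.sqrt(np.diag(fit.normalized_cov_params)) * inflate
    intercept, slope = fit.params
    if p_dist == "normal":
        p_slope = _norm_p(slope / se_slope)
        p_int = _norm_p(intercept / se_int)
    elif p_dist == "t":
        p_slope = float(2 * stats.t.sf(abs(slope / se_slope), J - 2))
        p_int = float(2 * stats.t.sf(abs(intercept / se_int), J - 2))
    else:
        raise ValueError(f"p_dist must be normal|t, got {p_dist!r}")
    return MREstimate(
        "egger", float(slope), float(se_slope), p_slope, J,
        intercept=float(intercept), intercept_se=float(se_int), intercept_pval=p_int,
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, p, r))


def _bootstrap_se(h: HarmonizedTable, statistic, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: redraw (γ*, Γ*) from normals centred on the
    observed effects with the per-SNP SEs, recompute the statistic."""
    g, seg, G, seG = _arrays(h)
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        gs = rng.normal(g, seg)
        Gs = rng.normal(G, seG)
        nz = gs != 0
        est[b] = statistic(Gs[nz] / gs[nz], seG[nz] / np.abs(gs[nz]))
    return float(est.std(ddof=1))


def weighted_median(h: HarmonizedTable, n_boot: int = 1000, seed: int = 0) -> MREstimate | None:
    """Weighted-median estimator with parametric-bootstrap SE.

    The estimate interpolates the inverse-variance-weighted empirical CDF of
    the Wald ratios at probability 0.5.
    """
    J = len(h)
    if J < MIN_SNPS["weighted_median"]:
        logger.warning("weighted median inapplicable with %d SNP(s); needs >= 3", J)
        return None
    wr = wald_ratios(h)
    beta = _weighted_median(wr["ratio"].to_numpy(), wr["se_ratio"].to_numpy() ** -2.0)
    se = _bootstrap_se(h, lambda r, s: _weighted_median(r, s**-2.0), n_boot, seed)
    return MREstimate("weighted_median", beta, se, _norm_p(beta / se), J)


def _mode_estimate(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    """Mode of a Gaussian-kernel density over the ratios, weights normalized;
    bandwidth is the modified Silverman rule 0.9·min(sd, MAD)·J^(−1/5) scaled
    by ``bandwidth_factor``."""
    if ratios.max() == ratios.min():
        return float(ratios[0])
    sd = float(np.std(ratios, ddof=1))
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    s = 0.9 * min(sd, mad) / len(ratios) ** 0.2
    if s == 0.0:
        # > half the ratios coincide: the discrete mode is that value
        vals, inv = np.unique(ratios, return_inverse=True)
        return float(vals[np.argmax(np.bincount(inv, weights=weights))])
    hgrid = max(1e-8, s * bandwidth_factor)
    grid = np.linspace(ratios.min() - 3 * hgrid, ratios.max() + 3 * hgrid, 2048)
    wn = weights / weights.sum()
    dens = stats.norm.pdf((grid[:, None] - ratios[None, :]) / hgrid) @ wn
    return float(grid[np.argmax(dens)])


def _mode(h: HarmonizedTable, method: str, bandwidth_factor: float, n_boot: int, seed: int) -> MREstimate | None:
    J = len(h)
    if J < MIN_SNPS[method]:
        logger.warning("%s inapplicable with %d SNP(s); needs >= 3", method, J)
        return None
    wr = wald_ratios(h)
    r = wr["ratio"].to_numpy()
    se_r = wr["se_ratio"].to_numpy()
    wfun = (lambda s: s**-2.0) if method == "weighted_mode" else (lambda s: np.ones_like(s))
    beta = _mode_estimate(r, wfun(se_r), bandwidth_factor)
    se = _bootstrap_se(h, lambda rr, ss: _mode_estimate(rr, wfun(ss), bandwidth_factor), n_boot, seed)
    return MREstimate(method, beta, se, _norm_p(beta / se), J)


def weighted_mode(h: HarmonizedTable, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0) -> MREstimate | None:
    """Mode-based estimate with inverse-variance kernel weights."""
    return _mode(h, "weighted_mode", bandwidth_factor, n_boot, seed)


def simple_mode(h: HarmonizedTable, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0) -> MREstimate | None:
    """Mode-based estimate with equal kernel weights."""
    return _mode(h, "simple_mode", bandwidth_factor, n_boot, seed)


def estimate_all(
    h: HarmonizedTable,
    seed: int = 0,
    n_boot: int = 1000,
    ivw_model: str = "random_multiplicative",
    bandwidth_factor: float = 1.0,
) -> dict[str, MREstimate | None]:
    """Run all five estimators; methods below their SNP minimum map to None.

    IVW is the primary analysis; the other four serve as pleiotropy-robust
    sensitivity estimators.
    """
    return {
        "ivw": ivw(h, model=ivw_model),
        "egger": mr_egger(h),
        "weighted_median": weighted_median(h, n_boot=n_boot, seed=seed),
        "weighted_mode": weighted_mode(h, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed),
        "simple_mode": simple_mode(h, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed),
    }


def estimates_to_frame(
    estimates: dict[str, MREstimate | None],
    exposure: str = "",
    outcome: str = "",
) -> pd.DataFrame:
    """Tidy results table (one row per method) mirroring the conventional
    report layout: exposure, outcome, method, nSNP, beta, se, OR, CI, P."""
    rows = []
    for method in METHODS:
        est = estimates.get(method)
        if est is None:
            rows.append({"exposure": exposure, "outcome": outcome, "method": method,
                         "nsnp": np.nan, "beta": np.nan, "se": np.nan, "or": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "pval": np.nan})
        else:
            rows.append({"exposure": exposure, "outcome": outcome, "method": method,
                         "nsnp": est.n_snp, "beta": est.beta, "se": est.se, "or": est.or_,
                         "ci_low": est.ci_low, "ci_high": est.ci_high, "pval": est.pval})
    return pd.DataFrame(rows)
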
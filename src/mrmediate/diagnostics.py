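"""Heterogeneity, pleiotropy, outlier and sensitivity analyses for MR fits.

Every exposure-outcome fit is accompanied by:

* Cochran's Q across the per-SNP Wald ratios (heterogeneity; chi-square with
  J−1 df under homogeneity);
* the MR-Egger intercept test (directional pleiotropy);
* MR-PRESSO — a simulation-based residual-sum-of-squares test that detects
  global horizontal pleiotropy, flags individual outlier variants
  (Bonferroni-adjusted), and checks whether removing them distorts the IVW
  estimate;
* leave-one-out IVW series (influence of single variants).

The pipeline treats heterogeneity/pleiotropy p-values > 0.05 as a passed
quality-control flag on a pair, mirroring common reporting practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import _arrays, ivw, mr_egger, wald_ratios
from .sumstats import HarmonizedTable

logger = logging.getLogger(__name__)


@dataclass
class HeterogeneityResult:
    q: float
    df: int
    pval: float


@dataclass
class EggerInterceptResult:
    intercept: float
    se: float
    pval: float


@dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    n_sim: int
    outlier_snp_ids: list[str]
    outlier_pvals: dict[str, float]
    distortion_pval: float | None
    beta_raw: float
    beta_corrected: float | None
    seed: int


@dataclass
class DiagnosticsReport:
    """Bundle of all diagnostics attached to one harmonized pair."""

    heterogeneity: HeterogeneityResult | None = None
    egger_intercept: EggerInterceptResult | None = None
    presso: PressoResult | None = None
    leave_one_out: pd.DataFrame | None = None

    def qc_pass(self, alpha: float = 0.05) -> bool:
        """True when no available heterogeneity/pleiotropy test rejects at alpha."""
        checks = []
        if self.heterogeneity is not None:
            checks.append(self.heterogeneity.pval > alpha)
        if self.egger_intercept is not None:
            checks.append(self.egger_intercept.pval > alpha)
        if self.presso is not None:
            checks.append(self.presso.global_pval > alpha)
        return all(checks)


def cochran_q(h: HarmonizedTable) -> HeterogeneityResult | None:
    """Cochran's Q over Wald ratios: Q = Σ w_j (ratio_j − β_fixed)² with
    w_j = 1/se_ratio_j²; chi-square with J−1 df. None below 2 SNPs."""
    if len(h) < 2:
        logger.warning("Cochran's Q inapplicable with %d SNP(s)", len(h))
        return None
    wr = wald_ratios(h)
    r = wr["ratio"].to_numpy()
    w = wr["se_ratio"].to_numpy() ** -2.0
    beta_fixed = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta_fixed) ** 2))
    df = len(r) - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))


def egger_intercept_test(h: HarmonizedTable) -> EggerInterceptResult | None:
    """Directional-pleiotropy test: the MR-Egger regression intercept and its
    two-sided test. None below 3 SNPs."""
    est = mr_egger(h)
    if est is None:
        return None
    return EggerInterceptResult(est.intercept, est.intercept_se, est.intercept_pval)


def leave_one_out(h: HarmonizedTable, model: str = "random_multiplicative") -> pd.DataFrame | None:
    """IVW refit excluding each SNP in turn; columns snp, beta, se, pval."""
    J = len(h)
    if J < 2:
        logger.warning("leave-one-out inapplicable with %d SNP(s)", J)
        return None
    rows = []
    mask = np.ones(J, dtype=bool)
    for j in range(J):
        mask[j] = False
        est = ivw(h.subset(mask), model=model)
        rows.append({"snp": h.df["snp"].iloc[j], "beta": est.beta, "se": est.se, "pval": est.pval})
        mask[j] = True
    return pd.DataFrame(rows)


def _loo_betas(g: np.ndarray, G: np.ndarray, seG: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW estimates leaving out each SNP, vectorized.

    ``G`` may be 2-d (n_sim, J); the result then has the same shape, each
    column j being the leave-j-out estimate for that simulated dataset.
    """
    w = 1.0 / seG**2
    num = g * G * w
    den = g**2 * w
    tot_num = num.sum(axis=-1, keepdims=True)
    tot_den = den.sum(axis=-1, keepdims=True)
    return (tot_num - num) / (tot_den - den)


def mr_presso(
    h: HarmonizedTable,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult | None:
    """MR-PRESSO global, outlier and distortion tests.

    The observed residual sum of squares uses leave-one-out predicted values
    (residual_j = Γ_j − γ_j·β_IVW(−j)); its null distribution comes from
    ``n_sim`` simulated outcome vectors Γ*_j ~ N(γ_j·β_IVW(−j), se_Γ_j), each
    evaluated with its own leave-one-out predictions. The global p-value is
    (1 + #{RSS* ≥ RSS_obs}) / (n_sim + 1), so it is never exactly zero.
    Per-SNP squared residuals are compared to their simulated counterparts and
    flagged at a Bonferroni-adjusted ``outlier_alpha``. When outliers are
    flagged, the distortion test compares the outlier-corrected IVW shift
    against shifts from removing random SNP sets of the same size.

    None below 4 SNPs.
    """
    J = len(h)
    if J < 4:
        logger.warning("MR-PRESSO inapplicable with %d SNP(s); needs >= 4", J)
        return None
    if n_sim < 100:
        logger.warning("MR-PRESSO with n_sim=%d (<100) gives a coarse null distribution", n_sim)
    g, _, G, seG = _arrays(h)
    rng = np.random.default_rng(seed)

    beta_loo = _loo_betas(g, G[None, :], seG)[0]
    resid_obs = G - g * beta_loo
    rss_obs = float(np.sum(resid_obs**2))

    G_sim = rng.normal(g * beta_loo, seG, size=(n_sim, J))
    beta_loo_sim = _loo_betas(g, G_sim, seG)
    resid_sim = G_sim - g * beta_loo_sim
    rss_sim = np.sum(resid_sim**2, axis=1)
    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    snp_pvals = (1 + np.sum(resid_sim**2 >= resid_obs**2, axis=0)) / (n_sim + 1)
    flagged = snp_pvals < outlier_alpha / J
    snps = h.df["snp"].to_numpy()
    outliers = [str(s) for s in snps[flagged]]
    outlier_pvals = {str(s): float(p) for s, p in zip(snps, snp_pvals)}

    beta_raw = ivw(h).beta
    beta_corrected = None
    distortion_pval = None
    m = int(flagged.sum())
    if 0 < m < J:
        beta_corrected = ivw(h.subset(~flagged)).beta
        shift_obs = beta_corrected - beta_raw
        shifts = np.empty(n_sim)
        for b in range(n_sim):
            drop = rng.choice(J, size=m, replace=False)
            keep = np.ones(J, dtype=bool)
            keep[drop] = False
            w = 1.0 / seG[keep] ** 2
            shifts[b] = np.sum(g[keep] * G[keep] * w) / np.sum(g[keep] ** 2 * w) - beta_raw
        distortion_pval = float((1 + np.sum(np.abs(shifts) >= abs(shift_obs))) / (n_sim + 1))

    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        n_sim=n_sim,
        outlier_snp_ids=outliers,
        outlier_pvals=outlier_pvals,
        distortion_pval=distortion_pval,
        beta_raw=beta_raw,
        beta_corrected=beta_corrected,
        seed=seed,
    )



def run_diagnostics(
    h: HarmonizedTable,
    presso_n_sim: int = 1000,
    presso_alpha: float = 0.05,
    seed: int = 0,
    loo_model: str = "random_multiplicative",
) -> DiagnosticsReport:
    """All diagnostics for one harmonized pair; inapplicable tests are None."""
    return DiagnosticsReport(
        heterogeneity=cochran_q(h),
        egger_intercept=egger_intercept_test(h),
        presso=mr_presso(h, n_sim=presso_n_sim, outlier_alpha=presso_alpha, seed=seed),
        leave_one_out=leave_one_out(h, model=loo_model),
    )
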
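"""Synthetic GWAS summary statistics under a known structural model.

The generator emulates the statistical shape of the study's three data
sources — a microbiome GWAS for the exposure, a circulating-protein pQTL
study for the mediator(s), and a disease case-control GWAS for the outcome —
directly at the summary level (no individual genotypes). Per SNP j:

    maf_j  ~ Uniform(maf_range)
    γ_j    ~ Normal(0, gamma_sd²)                 true SNP-exposure effect
    se(n)  = 1/sqrt(2·n·maf_j·(1−maf_j))          GWAS standard error at size n
    γ̂_j   = γ_j + Normal(0, se(n_exposure))

The mediator's true genetic effect is θ_xm·γ_j plus its own protein-specific
cis effects μ_j (mediator-specific SNPs), and the outcome follows the
structural equation

    Γ_j = θ_direct·γ_j + θ_my·(mediator effect)_j + α_j + δ_j

so the total exposure→outcome effect is θ_total = θ_direct + θ_xm·θ_my.
α_j is horizontal pleiotropy on a configurable fraction of exposure SNPs
(balanced, directional, or correlated with γ_j, i.e. InSIDE-violating);
δ_j are disease-specific effects carried by outcome-only SNPs, which feed
back onto the exposure with coefficient θ_reverse (zero by default, the
no-reverse-causation scenario). All three studies draw independent noise
(non-overlapping samples), every table contains the identical SNP set, and
everything is reproducible from (TruthParams, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LDMatrix
from .sumstats import SumStatTable

#: non-palindromic allele pairs assigned to synthetic SNPs, so harmonization
#: is label-resolvable by construction
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_PVAL_FLOOR = 1e-300


@dataclass
class TruthParams:
    """Ground-truth structural coefficients and study dimensions.

    Defaults mirror the emulated sources: exposure GWAS of n=18,340
    (microbiome consortium scale), mediator pQTL study of n=14,824, outcome
    case-control GWAS of n=198,166, with the headline decomposition
    θ_direct = 0.369 and θ_xm·θ_my = 0.2 × 0.09 = 0.018 (θ_total = 0.387,
    log-odds scale).
    """

    n_snps: int = 100
    theta_direct: float = 0.369
    theta_xm: float = 0.2
    theta_my: float = 0.09
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violating
    pleiotropy_sd: float = 0.05
    prop_invalid: float = 0.0
    n_exposure: int = 18_340
    n_mediator: int = 14_824
    n_outcome: int = 198_166
    gamma_sd: float = 0.06
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    # structure of the sources beyond the exposure's own variants
    n_mediator_snps: int = 0    #: protein-specific cis SNPs per mediator
    n_null_mediators: int = 0   #: extra mediators carrying no causal path
    n_outcome_snps: int = 0     #: disease-specific SNPs (reverse-MR instruments)
    theta_reverse: float = 0.0  #: outcome -> exposure feedback coefficient
    mu_sd: float | None = None  #: SD of mediator-specific effects (default gamma_sd)
    delta_sd: float | None = None  #: SD of outcome-specific effects (default gamma_sd)
    snp_prefix: str = "rs"

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"degenerate maf_range {self.maf_range}; need 0 < low < high < 1")
        if not 0.0 <= self.prop_invalid <= 1.0:
            raise ValueError(f"prop_invalid must be in [0,1], got {self.prop_invalid}")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) < 100:
                raise ValueError(f"{name} must be >= 100, got {getattr(self, name)}")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.theta_xm * self.theta_my


@dataclass
class SyntheticStudy:
    """One simulated two-sample setting; the first mediator carries the causal path."""

    exposure: SumStatTable
    mediators: list[SumStatTable] = field(default_factory=list)
    outcome: SumStatTable | None = None
    ld: LDMatrix | None = None
    truth: TruthParams | None = None


def _se_gwas(n: int, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), _PVAL_FLOOR, 1.0)


def _table(rng, snp, ea, oa, maf, true_beta, n, label, trait_type) -> SumStatTable:
    se = _se_gwas(n, maf)
    beta = true_beta + rng.normal(0.0, se)
    df = pd.DataFrame(
        {
            "snp": snp,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pval": _pvals(beta, se),
            "n": np.full(len(snp), n, dtype="int64"),
        }
    )
    return SumStatTable(df, trait_label=label, trait_type=trait_type)


def simulate_study(truth: TruthParams) -> SyntheticStudy:
    """Draw one complete study (exposure, mediators, outcome) from the truth.

    The SNP universe is the exposure's instruments-to-be, plus
    ``n_mediator_snps`` protein-specific SNPs per mediator, plus
    ``n_outcome_snps`` disease-specific SNPs; every table reports every SNP
    (null effects where a SNP does not act on that trait), as real GWAS do.
    """
    rng = np.random.default_rng(truth.seed)
    n_med_tables = 1 + truth.n_null_mediators
    n_total = truth.n_snps + n_med_tables * truth.n_mediator_snps + truth.n_outcome_snps
    mu_sd = truth.gamma_sd if truth.mu_sd is None else truth.mu_sd
    delta_sd = truth.gamma_sd if truth.delta_sd is None else truth.delta_sd

    snp = np.array([f"{truth.snp_prefix}{i + 1:06d}" for i in range(n_total)])
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), n_total)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    maf = rng.uniform(*truth.maf_range, n_total)

    # true effects on each latent trait
    gamma = np.zeros(n_total)
    gamma[: truth.n_snps] = rng.normal(0.0, truth.gamma_sd, truth.n_snps)

    mu = np.zeros((n_med_tables, n_total))
    offset = truth.n_snps
    for k in range(n_med_tables):
        mu[k, offset : offset + truth.n_mediator_snps] = rng.normal(0.0, mu_sd, truth.n_mediator_snps)
        offset += truth.n_mediator_snps

    delta = np.zeros(n_total)
    delta[offset : offset + truth.n_outcome_snps] = rng.normal(0.0, delta_sd, truth.n_outcome_snps)

    alpha = np.zeros(n_total)
    n_invalid = int(round(truth.prop_invalid * truth.n_snps))
    if truth.pleiotropy_mode != "none" and n_invalid > 0:
        invalid = rng.choice(truth.n_snps, size=n_invalid, replace=False)
        sd = truth.pleiotropy_sd
        if truth.pleiotropy_mode == "balanced":
            alpha[invalid] = rng.normal(0.0, sd, n_invalid)
        elif truth.pleiotropy_mode == "directional":
            # positive-mean pleiotropy expressed relative to the
            # exposure-increasing allele (the orientation Egger fits in),
            # with the offset dominating the spread
            alpha[invalid] = np.sign(gamma[invalid]) * rng.normal(sd, sd / 2.0, n_invalid)
        else:  # inside_violating: pleiotropy correlated with the instrument effect
            rho = 0.7
            z = rng.normal(0.0, 1.0, n_invalid)
            alpha[invalid] = sd * (rho * gamma[invalid] / truth.gamma_sd + np.sqrt(1 - rho**2) * z)

    exposure_true = gamma + truth.theta_reverse * delta
    mediator_true = [
        (truth.theta_xm * gamma if k == 0 else np.zeros(n_total)) + mu[k] for k in range(n_med_tables)
    ]
    outcome_true = truth.theta_direct * gamma + truth.theta_my * mediator_true[0] + alpha + delta

    exposure = _table(rng, snp, ea, oa, maf, exposure_true, truth.n_exposure, "exposure", "quantitative")
    mediators = [
        _table(rng, snp, ea, oa, maf, mediator_true[k], truth.n_mediator, f"mediator_{k + 1}", "quantitative")
        for k in range(n_med_tables)
    ]
    outcome = _table(rng, snp, ea, oa, maf, outcome_true, truth.n_outcome, "outcome", "binary")
    return SyntheticStudy(exposure=exposure, mediators=mediators, outcome=outcome, ld=None, truth=truth)


def simulate_null_battery(base: TruthParams, n_reps: int, seed: int = 0) -> list[SyntheticStudy]:
    """``n_reps`` independent studies from ``base`` with per-rep seeds derived
    deterministically from ``seed`` (the θ scenario — e.g. all-zero for a null
    battery — is whatever ``base`` encodes)."""
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_reps)
    return [simulate_study(replace(base, seed=int(s))) for s in child_seeds]


def simulate_ld_blocks(
    n_snps: int,
    block_size: int,
    within_r2: float,
    positions_per_kb: float = 1.0,
    seed: int = 0,
    snp_prefix: str = "rs",
) -> LDMatrix:
    """Block-diagonal LD fixture: ``within_r2`` between SNPs of the same block,
    zero between blocks; positions evenly spaced at ``positions_per_kb`` SNPs
    per kb on one chromosome, so the clumping window can cut within blocks.

    Deterministic by construction; ``seed`` is accepted for interface symmetry
    with the other generators.
    """
    if n_snps % block_size != 0:
        raise ValueError(f"block_size {block_size} must divide n_snps {n_snps}")
    if not 0.0 <= within_r2 <= 1.0:
        raise ValueError(f"within_r2 must be in [0,1], got {within_r2}")
    r2 = np.zeros((n_snps, n_snps))
    for start in range(0, n_snps, block_size):
        sl = slice(start, start + block_size)
        r2[sl, sl] = within_r2
    np.fill_diagonal(r2, 1.0)
    snp_ids = [f"{snp_prefix}{i + 1:06d}" for i in range(n_snps)]
    spacing_bp = 1000.0 / positions_per_kb
    positions = pd.DataFrame(
        {
            "snp": snp_ids,
            "chrom": np.ones(n_snps, dtype=int),
            "bp": (np.arange(n_snps) * spacing_bp).astype("int64"),
        }
    )
    return LDMatrix(snp_ids, r2, positions=positions)


def simulate_multi_exposure_study(
    truth: TruthParams,
    n_null_exposures: int = 0,
) -> tuple[list[SumStatTable], list[SumStatTable], SumStatTable, SyntheticStudy]:
    """One causal exposure plus ``n_null_exposures`` exposures with no effect,
    all sharing a single combined outcome GWAS (disjoint SNP universes per
    exposure, as for traits mapped in different consortia).

    Returns (exposures, mediators, combined outcome, the causal study).
    """
    active = simulate_study(truth)
    active.exposure.trait_label = "exposure_1"
    exposures = [active.exposure]
    outcome_parts = [active.outcome.df]
    null_seeds = np.random.default_rng([truth.seed, 0x5EED]).integers(0, 2**31 - 1, size=n_null_exposures)
    for i, s in enumerate(null_seeds):
        tr = replace(
            truth,
            theta_direct=0.0, theta_xm=0.0, theta_my=0.0, prop_invalid=0.0,
            n_null_mediators=0, n_mediator_snps=0, n_outcome_snps=0, theta_reverse=0.0,
            snp_prefix=f"n{i + 1}rs", seed=int(s),
        )
        s_null = simulate_study(tr)
        s_null.exposure.trait_label = f"exposure_{i + 2}"
        exposures.append(s_null.exposure)
        outcome_parts.append(s_null.outcome.df)
    outcome = SumStatTable(
        pd.concat(outcome_parts, ignore_index=True), trait_label="outcome", trait_type="binary"
    )
    return exposures, active.mediators, outcome, active
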
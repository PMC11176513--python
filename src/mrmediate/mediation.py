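"""Two-step mediation MR: decompose an exposure-outcome effect through a mediator.

Step 1 estimates the exposure→mediator effect (β_xm) with the exposure's
instruments; step 2 estimates the mediator→outcome effect (β_my) with the
mediator's instruments. The mediated (indirect) effect is the product of
coefficients β_xm·β_my, its standard error comes from the first-order delta
method,

    SE² = β_xm²·SE_my² + β_my²·SE_xm²,

and the direct effect is the total effect minus the mediated effect, so
direct + mediated = total holds exactly by construction. The proportion
mediated is mediated/total (undefined when the total effect is zero; flagged
"inconsistent mediation" when mediated and total effects have opposite sign).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .estimators import MREstimate, ivw
from .instruments import InstrumentCriteria, LDMatrix, select_instruments
from .sumstats import InputError, SumStatTable, harmonize

logger = logging.getLogger(__name__)

Z95 = 1.96


@dataclass
class MediationResult:
    """Total/direct/mediated decomposition for one exposure-mediator-outcome triplet."""

    exposure: str
    mediator: str
    outcome: str
    total_effect: float
    beta_xm: float
    se_xm: float
    beta_my: float
    se_my: float
    mediated_effect: float
    mediated_se: float
    mediated_ci_low: float
    mediated_ci_high: float
    direct_effect: float
    proportion_mediated: float | None
    inconsistent: bool

    @property
    def proportion_pct(self) -> float | None:
        """Proportion mediated as a percentage, reported to 3 decimals."""
        if self.proportion_mediated is None:
            return None
        return round(100.0 * self.proportion_mediated, 3)


def two_step_mediation(
    step1: MREstimate,
    step2: MREstimate,
    total: MREstimate,
    exposure: str = "",
    mediator: str = "",
    outcome: str = "",
) -> MediationResult:
    """Combine the three IVW estimates into a mediation decomposition."""
    mediated = step1.beta * step2.beta
    med_se = float(np.sqrt(step1.beta**2 * step2.se**2 + step2.beta**2 * step1.se**2))
    direct = total.beta - mediated
    if total.beta == 0:
        proportion = None
        inconsistent = False
        logger.warning("total effect is zero; proportion mediated undefined")
    else:
        proportion = mediated / total.beta
        inconsistent = mediated != 0 and np.sign(mediated) != np.sign(total.beta)
        if inconsistent:
            logger.warning(
                "inconsistent mediation for %s->%s->%s: mediated and total effects have opposite signs",
                exposure, mediator, outcome,
            )
    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        total_effect=total.beta,
        beta_xm=step1.beta,
        se_xm=step1.se,
        beta_my=step2.beta,
        se_my=step2.se,
        mediated_effect=mediated,
        mediated_se=med_se,
        mediated_ci_low=mediated - Z95 * med_se,
        mediated_ci_high=mediated + Z95 * med_se,
        direct_effect=direct,
        proportion_mediated=proportion,
        inconsistent=inconsistent,
    )


def decompose_effects(
    total: float,
    mediated: float | None = None,
    direct: float | None = None,
) -> dict:
    """Difference decomposition from any two of (total, mediated, direct).

    Useful for reproducing a published decomposition when only the point
    estimates are available: total = direct + mediated.
    """
    if (mediated is None) == (direct is None):
        raise ValueError("provide exactly one of mediated= or direct=")
    if mediated is None:
        mediated = total - direct
    else:
        direct = total - mediated
    proportion = mediated / total if total != 0 else None
    return {
        "total_effect": total,
        "direct_effect": direct,
        "mediated_effect": mediated,
        "proportion_mediated": proportion,
        "proportion_pct": None if proportion is None else round(100.0 * proportion, 3),
    }


def _instruments_match(a: SumStatTable, b: SumStatTable) -> bool:
    if set(a.df["snp"]) != set(b.df["snp"]):
        return False
    merged = a.df.merge(b.df, on="snp")
    return bool(np.allclose(merged["beta_x"], merged["beta_y"]) and np.allclose(merged["se_x"], merged["se_y"]))


def mediation_screen(
    exposure: SumStatTable,
    mediators: list[SumStatTable],
    outcome: SumStatTable,
    criteria: InstrumentCriteria | None = None,
    ld: LDMatrix | None = None,
    alpha: float = 0.05,
    ivw_model: str = "random_multiplicative",
) -> list[MediationResult]:
    """Screen candidate mediators of an exposure-outcome pair.

    A mediator qualifies when step 1 (exposure→mediator), step 2
    (mediator→outcome) and the exposure→outcome total effect are all
    significant at ``alpha`` (IVW). Mediators whose instrument set is
    indistinguishable from the exposure's (a relabeled copy) are flagged
    degenerate and excluded. Returns results for qualifying mediators only;
    an empty list when none qualifies.
    """
    criteria = criteria or InstrumentCriteria()
    exp_instr = select_instruments(exposure, criteria, ld)
    if len(exp_instr) == 0:
        raise InputError(f"no instruments for exposure {exposure.trait_label!r}")
    total = ivw(harmonize(exp_instr, outcome), model=ivw_model)
    if total.pval >= alpha:
        logger.info("total effect %s->%s not significant (p=%.3g); no mediator can qualify",
                    exposure.trait_label, outcome.trait_label, total.pval)
        return []

    results: list[MediationResult] = []
    for mediator in mediators:
        med_instr = select_instruments(mediator, criteria, ld)
        if len(med_instr) == 0:
            logger.info("mediator %s: no instruments, skipped", mediator.trait_label)
            continue
        if _instruments_match(exp_instr, med_instr):
            logger.warning(
                "mediator %s: instrument set identical to the exposure's (degenerate self-mediation), excluded",
                mediator.trait_label,
            )
            continue
        step1 = ivw(harmonize(exp_instr, mediator), model=ivw_model)
        step2 = ivw(harmonize(med_instr, outcome), model=ivw_model)
        if step1.pval < alpha and step2.pval < alpha:
            results.append(
                two_step_mediation(
                    step1, step2, total,
                    exposure=exposure.trait_label,
                    mediator=mediator.trait_label,
                    outcome=outcome.trait_label,
                )
            )
    if not results:
        logger.info("no qualifying mediator for %s -> %s", exposure.trait_label, outcome.trait_label)
    return results
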
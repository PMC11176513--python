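"""Orchestration of the four-stage bidirectional + mediation MR study.

Stage 1 screens every exposure against the outcome (forward MR); stage 2
re-runs MR with the roles swapped for the exposures found significant
(reverse MR, a check against reverse causation); stage 3 screens those
exposures against every candidate mediator; stage 4 screens mediators against
the outcome; finally, triplets whose step-1, step-2 and total effects are all
significant get a two-step mediation decomposition.

Significance is the nominal IVW p < alpha (default 0.05); a
Benjamini-Hochberg column is added to every screen table as a supplementary,
clearly non-primary adjustment. Heterogeneity/pleiotropy p-values > 0.05 are
summarised as a per-pair QC flag.
"""

from __future__ import annotations

import json
import logging
import re
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import __version__
from .diagnostics import DiagnosticsReport, run_diagnostics
from .estimators import MREstimate, estimate_all, estimates_to_frame
from .instruments import InstrumentCriteria, LDMatrix, read_ld, select_instruments
from .mediation import MediationResult, mediation_screen
from .simulate import TruthParams, simulate_multi_exposure_study
from .sumstats import InputError, SumStatTable, harmonize, read_sumstats

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDE_PATTERN = r"unknown|unclassified|uncultured|unspecified"


@dataclass
class ScreenResult:
    """One exposure-outcome pair: all estimates, diagnostics, and the verdicts."""

    exposure_label: str
    outcome_label: str
    estimates: dict[str, MREstimate | None]
    diagnostics: DiagnosticsReport
    n_instruments: int
    significant: bool
    qc_pass: bool


def _pair_seed(seed: int, exposure: str, outcome: str) -> int:
    """Per-pair seed, stable under reordering of the input collections."""
    return (seed ^ zlib.crc32(f"{exposure}|{outcome}".encode())) % (2**31 - 1)


def screen_pair(
    exposure: SumStatTable,
    outcome: SumStatTable,
    criteria: InstrumentCriteria | None = None,
    ld: LDMatrix | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    n_boot: int = 1000,
    presso_n_sim: int = 1000,
) -> ScreenResult | None:
    """Instrument selection, harmonization, all estimators and diagnostics for
    one pair. Returns None (with a log entry) when no instrument survives or
    the studies share no SNP."""
    criteria = criteria or InstrumentCriteria()
    instruments = select_instruments(exposure, criteria, ld)
    if len(instruments) == 0:
        logger.info("skipping %s -> %s: zero instruments", exposure.trait_label, outcome.trait_label)
        return None
    try:
        h = harmonize(instruments, outcome)
    except InputError as exc:
        logger.info("skipping %s -> %s: %s", exposure.trait_label, outcome.trait_label, exc)
        return None
    if len(h) == 0:
        logger.info("skipping %s -> %s: no SNP survived harmonization",
                    exposure.trait_label, outcome.trait_label)
        return None
    pseed = _pair_seed(seed, exposure.trait_label, outcome.trait_label)
    estimates = estimate_all(h, seed=pseed, n_boot=n_boot)
    diag = run_diagnostics(h, presso_n_sim=presso_n_sim, seed=pseed)
    ivw_est = estimates["ivw"]
    return ScreenResult(
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        estimates=estimates,
        diagnostics=diag,
        n_instruments=len(h),
        significant=bool(ivw_est.pval < alpha),
        qc_pass=diag.qc_pass(),
    )


def run_forward_screen(
    exposures: list[SumStatTable],
    outcome: SumStatTable,
    criteria: InstrumentCriteria | None = None,
    ld: LDMatrix | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    n_boot: int = 1000,
    presso_n_sim: int = 1000,
) -> list[ScreenResult]:
    """Stage 1: every exposure against the outcome."""
    if not exposures:
        raise InputError("forward screen needs at least one exposure")
    results = []
    for exposure in exposures:
        res = screen_pair(exposure, outcome, criteria, ld, alpha, seed, n_boot, presso_n_sim)
        if res is not None:
            results.append(res)
    return results


def run_reverse_mr(
    outcome_as_exposure: SumStatTable,
    targets: list[SumStatTable],
    criteria: InstrumentCriteria | None = None,
    ld: LDMatrix | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    n_boot: int = 1000,
    presso_n_sim: int = 1000,
) -> list[ScreenResult]:
    """Stage 2: the disease trait instrumented as the exposure, against each
    previously significant trait. Targets identical to the instrumenting trait
    are degenerate and skipped with a warning."""
    results = []
    for target in targets:
        if target.equals(outcome_as_exposure):
            logger.warning("reverse MR target %s is identical to the exposure trait; degenerate, skipped",
                           target.trait_label)
            continue
        res = screen_pair(outcome_as_exposure, target, criteria, ld, alpha, seed, n_boot, presso_n_sim)
        if res is not None:
            results.append(res)
    return results


def screens_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Long-format report: one row per (pair, method), with diagnostics columns
    repeated per pair and a supplementary BH-adjusted column on the IVW rows."""
    columns = ["exposure", "outcome", "method", "nsnp", "beta", "se", "or", "ci_low",
               "ci_high", "pval", "q", "q_df", "q_pval", "egger_intercept",
               "egger_intercept_pval", "presso_global_pval", "presso_outliers",
               "significant", "qc_pass", "pval_bh"]
    if not results:
        return pd.DataFrame(columns=columns)
    frames = []
    for r in sorted(results, key=lambda r: (r.exposure_label, r.outcome_label)):
        frame = estimates_to_frame(r.estimates, exposure=r.exposure_label, outcome=r.outcome_label)
        het = r.diagnostics.heterogeneity
        egg = r.diagnostics.egger_intercept
        presso = r.diagnostics.presso
        frame["q"] = het.q if het else np.nan
        frame["q_df"] = het.df if het else np.nan
        frame["q_pval"] = het.pval if het else np.nan
        frame["egger_intercept"] = egg.intercept if egg else np.nan
        frame["egger_intercept_pval"] = egg.pval if egg else np.nan
        frame["presso_global_pval"] = presso.global_pval if presso else np.nan
        frame["presso_outliers"] = ";".join(presso.outlier_snp_ids) if presso else ""
        frame["significant"] = r.significant
        frame["qc_pass"] = r.qc_pass
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    ivw_rows = out["method"] == "ivw"
    out["pval_bh"] = np.nan
    if ivw_rows.sum() > 0:
        out.loc[ivw_rows, "pval_bh"] = multipletests(out.loc[ivw_rows, "pval"], method="fdr_bh")[1]
    return out


def mediation_to_frame(results: list[MediationResult]) -> pd.DataFrame:
    rows = [
        {
            "exposure": m.exposure,
            "mediator": m.mediator,
            "outcome": m.outcome,
            "total": m.total_effect,
            "direct": m.direct_effect,
            "mediated": m.mediated_effect,
            "mediated_ci_low": m.mediated_ci_low,
            "mediated_ci_high": m.mediated_ci_high,
            "proportion_pct": m.proportion_pct,
            "inconsistent": m.inconsistent,
        }
        for m in sorted(results, key=lambda m: (m.exposure, m.mediator))
    ]
    cols = ["exposure", "mediator", "outcome", "total", "direct", "mediated",
            "mediated_ci_low", "mediated_ci_high", "proportion_pct", "inconsistent"]
    return pd.DataFrame(rows, columns=cols)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _criteria_from_config(cfg: dict) -> InstrumentCriteria:
    c = cfg.get("criteria", {}) or {}
    return InstrumentCriteria(
        p_threshold=float(c.get("p_threshold", 1e-5)),
        clump_r2=float(c.get("clump_r2", 0.001)),
        clump_window_kb=int(c.get("clump_window_kb", 10_000)),
        f_min=float(c.get("f_min", 10.0)),
    )


def _load_inputs(cfg: dict, seed: int):
    """Either read user-supplied summary-statistics files or simulate a study
    from the ``synthetic`` block."""
    if "inputs" in cfg:
        inp = cfg["inputs"]
        exposures = [read_sumstats(p, trait_label=Path(p).stem) for p in inp["exposures"]]
        mediators = [read_sumstats(p, trait_label=Path(p).stem) for p in inp.get("mediators", [])]
        outcome = read_sumstats(inp["outcome"], trait_label=Path(inp["outcome"]).stem, trait_type="binary")
        ld = None
        if inp.get("ld"):
            ld = read_ld(inp["ld"], positions_path=inp.get("ld_positions"))
        return exposures, mediators, outcome, ld
    syn = dict(cfg.get("synthetic", {}) or {})
    n_null_exposures = int(syn.pop("n_null_exposures", 0))
    truth = TruthParams(seed=seed, **syn)
    exposures, mediators, outcome, _ = simulate_multi_exposure_study(truth, n_null_exposures)
    return exposures, mediators, outcome, None


def run_full_study(config, out_dir=None, seed: int | None = None) -> dict:
    """Execute the full study and write the report bundle.

    Writes ``forward.tsv``, ``reverse.tsv``, ``step1.tsv``, ``step2.tsv``,
    ``mediation.tsv`` and ``run_log.json`` under ``out_dir``; returns the
    in-memory bundle. Stages with zero survivors cause downstream stages to
    be skipped and recorded as such — not an error.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    out_dir = Path(out_dir or cfg.get("out_dir", "mr_results"))
    out_dir.mkdir(parents=True, exist_ok=True)
    alpha = float(cfg.get("alpha", 0.05))
    n_boot = int(cfg.get("n_boot", 1000))
    presso_n_sim = int(cfg.get("presso_n_sim", 1000))
    criteria = _criteria_from_config(cfg)
    mediator_mode = cfg.get("mediator_mode", "unconditional")
    pattern = cfg.get("exclude_label_pattern", DEFAULT_EXCLUDE_PATTERN)

    exposures, mediators, outcome, ld = _load_inputs(cfg, seed)
    counts: dict[str, dict[str, int]] = {}

    def book(stage: str, n_in: int, n_out: int) -> None:
        counts[stage] = {"input": n_in, "rejected": n_in - n_out, "output": n_out}
        assert counts[stage]["input"] - counts[stage]["rejected"] == counts[stage]["output"]

    # trait-name hygiene: drop traits lacking specific nomenclature
    rx = re.compile(pattern, re.IGNORECASE) if pattern else None
    named = [e for e in exposures if rx is None or not rx.search(e.trait_label)]
    book("label_filter", len(exposures), len(named))
    exposures = named

    bundle: dict = {"config": cfg, "seed": seed}

    forward = run_forward_screen(exposures, outcome, criteria, ld, alpha, seed, n_boot, presso_n_sim)
    book("forward_screen", len(exposures), len(forward))
    screens_to_frame(forward).to_csv(out_dir / "forward.tsv", sep="\t", index=False, na_rep="NA")
    bundle["forward"] = forward
    significant = [r.exposure_label for r in forward if r.significant]
    sig_tables = [e for e in exposures if e.trait_label in significant]
    book("significant_exposures", len(forward), len(sig_tables))

    reverse: list[ScreenResult] = []
    step1: list[ScreenResult] = []
    step2: list[ScreenResult] = []
    mediation_results: list[MediationResult] = []
    if not sig_tables:
        logger.warning("no significant forward exposure; downstream stages skipped")
        counts["reverse_mr"] = counts["mediator_step1"] = counts["mediator_step2"] = \
            counts["mediation"] = {"input": 0, "rejected": 0, "output": 0}
    else:
        reverse = run_reverse_mr(outcome, sig_tables, criteria, ld, alpha, seed, n_boot, presso_n_sim)
        book("reverse_mr", len(sig_tables), len(reverse))

        for exposure in sig_tables:
            for mediator in mediators:
                res = screen_pair(exposure, mediator, criteria, ld, alpha, seed, n_boot, presso_n_sim)
                if res is not None:
                    step1.append(res)
        book("mediator_step1", len(sig_tables) * len(mediators), len(step1))

        if mediator_mode == "conditional":
            step1_sig = {r.outcome_label for r in step1 if r.significant}
            step2_mediators = [m for m in mediators if m.trait_label in step1_sig]
        else:
            step2_mediators = list(mediators)
        for mediator in step2_mediators:
            res = screen_pair(mediator, outcome, criteria, ld, alpha, seed, n_boot, presso_n_sim)
            if res is not None:
                step2.append(res)
        book("mediator_step2", len(step2_mediators), len(step2))

        for exposure in sig_tables:
            mediation_results.extend(
                mediation_screen(exposure, mediators, outcome, criteria, ld, alpha)
            )
        book("mediation", len(sig_tables) * len(mediators), len(mediation_results))

    for name, res in (("reverse", reverse), ("step1", step1), ("step2", step2)):
        screens_to_frame(res).to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
    mediation_to_frame(mediation_results).to_csv(out_dir / "mediation.tsv", sep="\t", index=False, na_rep="NA")
    bundle.update(reverse=reverse, step1=step1, step2=step2, mediation=mediation_results, counts=counts)

    run_log = {
        "package": "mrmediate",
        "version": __version__,
        "seed": seed,
        "alpha": alpha,
        "criteria": {
            "p_threshold": criteria.p_threshold,
            "clump_r2": criteria.clump_r2,
            "clump_window_kb": criteria.clump_window_kb,
            "f_min": criteria.f_min,
        },
        "mediator_mode": mediator_mode,
        "counts": counts,
        "significant_exposures": sorted(significant),
        "qualifying_mediators": sorted({m.mediator for m in mediation_results}),
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    bundle["run_log"] = run_log
    return bundle
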
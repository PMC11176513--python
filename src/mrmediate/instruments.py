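"""Instrumental-variable selection for two-sample MR.

Candidate instruments are genome-wide associations passing a p-value threshold
(default p < 1e-5, the relaxed threshold customary for microbiome GWAS), pruned
to approximate linkage-equilibrium by greedy LD clumping (r² < 0.001 within
10,000 kb), and screened for weak-instrument bias with the per-SNP F statistic
(F > 10 retained).

Instrument strength uses the proportion of trait variance a SNP explains,

    R² = 2 β² EAF (1 − EAF) / (2 β² EAF (1 − EAF) + 2 SE² N EAF (1 − EAF))

which simplifies algebraically to β² / (β² + N·SE²), and

    F = R² (N − 2) / (1 − R²).

Strength is computed on the exposure study (pre-harmonization) because the
formula uses the exposure β, SE, EAF and N.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import InputError, SumStatTable

logger = logging.getLogger(__name__)


@dataclass
class InstrumentCriteria:
    """Thresholds governing instrument selection."""

    p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if not 0 <= self.clump_r2 <= 1:
            raise ValueError(f"clump_r2 must be in [0,1], got {self.clump_r2}")
        if self.clump_window_kb <= 0:
            raise ValueError(f"clump_window_kb must be positive, got {self.clump_window_kb}")


@dataclass
class LDMatrix:
    """Squared-correlation matrix between SNPs, standing in for a reference panel.

    ``positions``, when given, is a DataFrame with columns ``snp, chrom, bp``
    and enables the clumping distance window; without positions every pair is
    treated as within-window.
    """

    snp_ids: list[str]
    r2: np.ndarray
    positions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 must be {k}x{k}, got {self.r2.shape}")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0,1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if self.positions is not None:
            self.positions = self.positions.set_index("snp") if "snp" in self.positions.columns else self.positions

    def index_of(self, snp: str) -> int:
        try:
            return self._index[snp]
        except KeyError:
            raise InputError(f"snp {snp!r} absent from LD matrix") from None


def write_ld(ld: LDMatrix, path, positions_path=None) -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t", index_label="snp")
    if positions_path is not None and ld.positions is not None:
        ld.positions.to_csv(positions_path, sep="\t", index_label="snp")


def read_ld(path, positions_path=None) -> LDMatrix:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    positions = None
    if positions_path is not None:
        positions = pd.read_csv(positions_path, sep="\t")
    return LDMatrix(list(mat.columns.astype(str)), mat.to_numpy(float), positions=positions)


def select_by_pvalue(table: SumStatTable, p_threshold: float) -> SumStatTable:
    """Rows with pval strictly below the threshold, original order preserved."""
    mask = (table.df["pval"] < p_threshold).to_numpy()
    if not mask.any():
        logger.info("%s: no SNP passes p < %g", table.trait_label, p_threshold)
    return table.subset(mask)


def ld_clump(candidates: SumStatTable, ld: LDMatrix, criteria: InstrumentCriteria) -> SumStatTable:
    """Greedy LD clumping of candidate instruments.

    Candidates are visited in ascending p-value order (ties broken
    lexicographically by snp id, for determinism); each is accepted unless its
    r² to an already-accepted SNP within the clumping window meets or exceeds
    ``clump_r2``. Pairs on different chromosomes, or further apart than
    ``clump_window_kb`` (boundary inclusive), are never clumped.
    """
    df = candidates.df
    idx = np.array([ld.index_of(s) for s in df["snp"]])
    order = df.assign(_i=np.arange(len(df))).sort_values(["pval", "snp"], kind="mergesort")["_i"].to_numpy()

    if ld.positions is not None:
        pos = ld.positions.loc[df["snp"]]
        chrom = pos["chrom"].to_numpy()
        bp = pos["bp"].to_numpy(float)
    else:
        chrom = bp = None

    accepted: list[int] = []
    for i in order:
        clash = False
        for j in accepted:
            if chrom is not None:
                if chrom[i] != chrom[j] or abs(bp[i] - bp[j]) > criteria.clump_window_kb * 1000:
                    continue
            if ld.r2[idx[i], idx[j]] >= criteria.clump_r2:
                clash = True
                break
        if not clash:
            accepted.append(i)
    keep = np.zeros(len(df), dtype=bool)
    keep[accepted] = True
    logger.info("%s: clumping retained %d/%d candidates", candidates.trait_label, keep.sum(), len(df))
    return candidates.subset(keep)


def variance_explained(beta: float, eaf: float, se: float, n: int) -> float:
    """Proportion of trait variance explained by one SNP.

    Computed with the full allele-frequency form (see module docstring); the
    EAF factors cancel, so the value equals β²/(β² + N·SE²) and is symmetric
    in EAF ↔ 1−EAF.
    """
    if not 0 < eaf < 1:
        raise ValueError(f"eaf must lie strictly in (0,1), got {eaf}")
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    num = 2.0 * beta**2 * eaf * (1.0 - eaf)
    den = num + 2.0 * se**2 * n * eaf * (1.0 - eaf)
    return num / den


def f_statistic(r2: float, n: int) -> float:
    """Single-instrument F statistic, F = R²(N−2)/(1−R²); F > 10 is the
    conventional bar against weak-instrument bias."""
    if not 0 <= r2 < 1:
        raise ValueError(f"r2 must lie in [0,1), got {r2}")
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    return r2 * (n - 2) / (1.0 - r2)


def instrument_strength(table: SumStatTable) -> pd.DataFrame:
    """Per-SNP R² and F for every row with a usable EAF.

    Returns a DataFrame ``snp, r2_explained, f_stat``; rows with missing EAF
    are omitted (strength incomputable) with a warning.
    """
    df = table.df
    usable = df["eaf"].notna().to_numpy()
    if (~usable).any():
        logger.warning(
            "%s: %d SNP(s) lack EAF; instrument strength incomputable, excluded",
            table.trait_label, int((~usable).sum()),
        )
    sub = df.loc[usable]
    r2 = np.array(
        [variance_explained(b, f, s, int(n)) for b, f, s, n in zip(sub["beta"], sub["eaf"], sub["se"], sub["n"])]
    )
    f = np.array([f_statistic(r, int(n)) for r, n in zip(r2, sub["n"])])
    return pd.DataFrame({"snp": sub["snp"].to_numpy(), "r2_explained": r2, "f_stat": f})


def filter_weak(instruments: SumStatTable, f_min: float = 10.0) -> SumStatTable:
    """Keep instruments whose F statistic strictly exceeds ``f_min``."""
    strength = instrument_strength(instruments)
    strong = set(strength.loc[strength["f_stat"] > f_min, "snp"])
    mask = instruments.df["snp"].isin(strong).to_numpy()
    return instruments.subset(mask)


def select_instruments(
    table: SumStatTable,
    criteria: InstrumentCriteria | None = None,
    ld: LDMatrix | None = None,
) -> SumStatTable:
    """Full instrument-selection cascade: p-value filter, LD clumping (when an
    LD matrix is supplied), weak-instrument filter."""
    criteria = criteria or InstrumentCriteria()
    selected = select_by_pvalue(table, criteria.p_threshold)
    if ld is not None and len(selected) > 0:
        selected = ld_clump(selected, ld, criteria)
    if len(selected) > 0 and math.isfinite(criteria.f_min):
        selected = filter_weak(selected, criteria.f_min)
    elif not math.isfinite(criteria.f_min):
        selected = selected.subset(np.zeros(len(selected), dtype=bool))
    return selected
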
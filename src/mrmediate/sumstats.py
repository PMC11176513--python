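"""GWAS summary-statistics tables: reading, validation, writing, and allele harmonization.

The universal currency of the pipeline is a table with one row per variant
(biallelic SNP) carrying the association of that variant with a single trait:
effect allele, other allele, effect-allele frequency (EAF), effect size
``beta`` (log-odds for binary traits, SD units for quantitative traits), its
standard error, p-value, and GWAS sample size.

Two-sample Mendelian randomization needs the SNP-exposure and SNP-outcome
effects expressed relative to the *same* effect allele; :func:`harmonize`
aligns two tables, flipping outcome effect signs where the studies coded
opposite alleles and resolving or discarding strand-ambiguous (palindromic)
variants by allele-frequency inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order for summary-statistics files
CANONICAL_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]
MANDATORY_COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se", "pval", "n"]

NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
NA_REP = "NA"

ACTION_UNCHANGED = "unchanged"
ACTION_FLIPPED = "flipped"
ACTION_DROPPED_PALINDROMIC = "dropped_palindromic"
ACTION_DROPPED_MISMATCH = "dropped_mismatch"


class ConfigurationError(ValueError):
    """A required column or configuration key is missing or malformed."""


class InputError(ValueError):
    """Input data cannot be used (empty table, no shared SNPs, ...)."""


def is_palindromic(effect_allele: pd.Series | np.ndarray, other_allele) -> np.ndarray:
    """A/T and C/G variants: the two alleles are reverse complements, so strand
    cannot be inferred from allele labels alone."""
    ea = np.asarray(effect_allele, dtype=object)
    oa = np.asarray(other_allele, dtype=object)
    return np.array([COMPLEMENT.get(a) == b for a, b in zip(ea, oa)])


def _record_validity_mask(df: pd.DataFrame) -> pd.Series:
    ea = df["effect_allele"].astype(str)
    oa = df["other_allele"].astype(str)
    ok = ea.isin(NUCLEOTIDES) & oa.isin(NUCLEOTIDES) & (ea != oa)
    ok &= pd.to_numeric(df["se"], errors="coerce") > 0
    pval = pd.to_numeric(df["pval"], errors="coerce")
    ok &= (pval > 0) & (pval <= 1)
    n = pd.to_numeric(df["n"], errors="coerce")
    ok &= (n > 0) & (n == np.floor(n))
    ok &= pd.to_numeric(df["beta"], errors="coerce").notna()
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    ok &= df["eaf"].isna() | ((eaf > 0) & (eaf < 1))
    return ok


@dataclass
class SumStatTable:
    """Ordered collection of per-SNP summary statistics for one trait.

    ``df`` holds the canonical columns (:data:`CANONICAL_COLUMNS`); ``eaf`` may
    be NaN. SNP identifiers must be unique within a table.
    """

    df: pd.DataFrame
    trait_label: str = ""
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"missing mandatory column(s): {missing}")
        if "eaf" not in self.df.columns:
            self.df = self.df.assign(eaf=np.nan)
        if self.trait_type not in ("binary", "quantitative"):
            raise ConfigurationError(f"trait_type must be binary|quantitative, got {self.trait_type!r}")
        if self.df["snp"].duplicated().any():
            dups = self.df.loc[self.df["snp"].duplicated(), "snp"].head().tolist()
            raise InputError(f"duplicate snp ids in table {self.trait_label!r}: {dups} ...")
        self.df = self.df.loc[:, CANONICAL_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def subset(self, mask_or_snps) -> "SumStatTable":
        """New table restricted to a boolean mask or an iterable of snp ids,
        preserving row order."""
        if isinstance(mask_or_snps, (pd.Series, np.ndarray)) and getattr(mask_or_snps, "dtype", None) == bool:
            sub = self.df.loc[np.asarray(mask_or_snps)]
        else:
            keep = set(mask_or_snps)
            sub = self.df.loc[self.df["snp"].isin(keep)]
        return SumStatTable(sub.copy(), trait_label=self.trait_label, trait_type=self.trait_type)

    def equals(self, other: "SumStatTable") -> bool:
        return (
            self.trait_label == other.trait_label
            and self.trait_type == other.trait_type
            and self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))
        )


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    sep: str = "\t",
    trait_label: str = "",
    trait_type: str = "quantitative",
) -> SumStatTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    column_map
        Mapping ``canonical_name -> file_column_name`` for files not using the
        canonical header. Unmapped canonical names are looked up verbatim.
        There is deliberately no header auto-sniffing.

    Rows violating the per-record invariants (non-ACGT or identical alleles —
    which also rejects indels and multi-allelic variants — ``se <= 0``, p-value
    outside (0, 1], EAF outside (0, 1), non-integral n) are dropped with a
    logged count.
    """
    raw = pd.read_csv(path, sep=sep, na_values=[NA_REP], dtype={0: str})
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        raw = raw.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory column(s) {missing}; provide a column_map")
    if len(raw) == 0:
        raise InputError(f"{path}: empty summary-statistics table")
    if "eaf" not in raw.columns:
        raw["eaf"] = np.nan
    raw["snp"] = raw["snp"].astype(str)
    raw["effect_allele"] = raw["effect_allele"].astype(str).str.upper()
    raw["other_allele"] = raw["other_allele"].astype(str).str.upper()
    ok = _record_validity_mask(raw)
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("%s: rejected %d/%d rows violating record invariants", path, n_rejected, len(raw))
    clean = raw.loc[ok].copy()
    clean["n"] = pd.to_numeric(clean["n"]).astype("int64")
    for col in ("eaf", "beta", "se", "pval"):
        clean[col] = pd.to_numeric(clean[col]).astype(float)
    return SumStatTable(clean, trait_label=trait_label, trait_type=trait_type)


def write_sumstats(table: SumStatTable, path) -> None:
    """Write a table as TSV with the canonical column order; missing EAF is the
    sentinel ``NA``. ``read_sumstats(write_sumstats(t)) == t``."""
    if len(table) == 0:
        raise InputError("refusing to write an empty summary-statistics table")
    out = table.df.copy()
    out["n"] = out["n"].astype("int64")
    out.to_csv(path, sep="\t", index=False, na_rep=NA_REP, columns=CANONICAL_COLUMNS)


# ---------------------------------------------------------------------------
# harmonization


@dataclass
class HarmonizedTable:
    """Exposure-outcome (or exposure-mediator) pairs on a common effect allele.

    ``df`` columns: ``snp, gamma, se_gamma, Gamma, se_Gamma, eaf_exposure,
    eaf_outcome, action`` where ``gamma`` is the SNP-exposure effect and
    ``Gamma`` the SNP-outcome effect after alignment. Only retained rows live
    in ``df``; discarded rows and the reason are kept in ``dropped``.
    """

    df: pd.DataFrame
    exposure_label: str = ""
    outcome_label: str = ""
    dropped: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["snp", "action"]))

    def __post_init__(self) -> None:
        if self.df["action"].str.startswith("dropped").any():
            raise InputError("retained harmonized rows must not carry a dropped_* action")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "HarmonizedTable":
        return HarmonizedTable(
            self.df.loc[np.asarray(mask)].copy(),
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
        )


HARMONIZED_COLUMNS = ["snp", "gamma", "se_gamma", "Gamma", "se_Gamma", "eaf_exposure", "eaf_outcome", "action"]


def write_harmonized(h: HarmonizedTable, path) -> None:
    h.df.to_csv(path, sep="\t", index=False, na_rep=NA_REP, columns=HARMONIZED_COLUMNS)


def read_harmonized(path) -> HarmonizedTable:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], dtype={"snp": str, "action": str})
    return HarmonizedTable(df)


def harmonize(
    exposure: SumStatTable,
    outcome: SumStatTable,
    palindromic_eaf_window: float = 0.08,
) -> HarmonizedTable:
    """Align the outcome study's effects to the exposure study's effect alleles.

    Decision table, per shared SNP (exposure alleles EA/OA, outcome EA'/OA'):

    * same alleles, same orientation (or their reverse complement, for
      non-palindromic SNPs) -> retained unchanged;
    * swapped alleles (or complement-swapped) -> outcome beta negated and
      eaf replaced by 1-eaf (``flipped``);
    * palindromic SNP (A/T or C/G): allele labels cannot resolve strand, so
      orientation is inferred from allele frequencies. If either EAF is
      missing or falls inside ``[0.5 - w, 0.5 + w]`` (default w = 0.08, i.e.
      drop window [0.42, 0.58]) the SNP is dropped; otherwise the outcome is
      first aligned nominally by labels, then additionally flipped when the
      two frequencies sit on opposite sides of 0.5;
    * allele sets that cannot be reconciled -> ``dropped_mismatch``.

    Raises :class:`InputError` when the two tables share no SNP.
    """
    merged = exposure.df.merge(outcome.df, on="snp", suffixes=("_x", "_y"), how="inner")
    if len(merged) == 0:
        raise InputError(
            f"no shared SNPs between {exposure.trait_label!r} and {outcome.trait_label!r}"
        )

    ea_x = merged["effect_allele_x"].to_numpy(dtype=object)
    oa_x = merged["other_allele_x"].to_numpy(dtype=object)
    ea_y = merged["effect_allele_y"].to_numpy(dtype=object)
    oa_y = merged["other_allele_y"].to_numpy(dtype=object)
    comp_ea_y = np.array([COMPLEMENT[a] for a in ea_y], dtype=object)
    comp_oa_y = np.array([COMPLEMENT[a] for a in oa_y], dtype=object)

    palin = is_palindromic(ea_x, oa_x)
    same = (ea_y == ea_x) & (oa_y == oa_x)
    swap = (ea_y == oa_x) & (oa_y == ea_x)
    comp_same = (comp_ea_y == ea_x) & (comp_oa_y == oa_x)
    comp_swap = (comp_ea_y == oa_x) & (comp_oa_y == ea_x)

    gamma = merged["beta_x"].to_numpy(float)
    se_gamma = merged["se_x"].to_numpy(float)
    Gamma = merged["beta_y"].to_numpy(float).copy()
    se_Gamma = merged["se_y"].to_numpy(float)
    eaf_x = merged["eaf_x"].to_numpy(float)
    eaf_y = merged["eaf_y"].to_numpy(float).copy()

    action = np.full(len(merged), ACTION_DROPPED_MISMATCH, dtype=object)

    # non-palindromic: allele labels (optionally through the complement) decide
    np_unchanged = ~palin & (same | comp_same)
    np_flip = ~palin & ~np_unchanged & (swap | comp_swap)
    action[np_unchanged] = ACTION_UNCHANGED
    action[np_flip] = ACTION_FLIPPED

    # palindromic: same == comp_swap and swap == comp_same, labels are ambiguous
    pal_match = palin & (same | swap)
    w = palindromic_eaf_window
    informative = (
        pal_match
        & ~np.isnan(eaf_x)
        & ~np.isnan(eaf_y)
        & (np.abs(eaf_x - 0.5) > w)
        & (np.abs(eaf_y - 0.5) > w)
    )
    action[pal_match & ~informative] = ACTION_DROPPED_PALINDROMIC
    # nominal label alignment, then frequency-side comparison
    pal_aligned_eaf = np.where(swap, 1.0 - eaf_y, eaf_y)
    freq_flip = informative & ((eaf_x - 0.5) * (pal_aligned_eaf - 0.5) < 0)
    pal_label_flip = informative & swap
    pal_net_flip = informative & (freq_flip ^ pal_label_flip)
    action[informative] = ACTION_UNCHANGED
    action[pal_net_flip] = ACTION_FLIPPED

    flip = action == ACTION_FLIPPED
    Gamma[flip] = -Gamma[flip]
    eaf_y[flip] = 1.0 - eaf_y[flip]

    out = pd.DataFrame(
        {
            "snp": merged["snp"],
            "gamma": gamma,
            "se_gamma": se_gamma,
            "Gamma": Gamma,
            "se_Gamma": se_Gamma,
            "eaf_exposure": eaf_x,
            "eaf_outcome": eaf_y,
            "action": action,
        }
    )
    keep = ~pd.Series(action).str.startswith("dropped").to_numpy()
    dropped = out.loc[~keep, ["snp", "action"]].reset_index(drop=True)
    n_drop = len(dropped)
    if n_drop:
        logger.info(
            "harmonize(%s, %s): dropped %d/%d shared SNPs (%s)",
            exposure.trait_label, outcome.trait_label, n_drop, len(out),
            dropped["action"].value_counts().to_dict(),
        )
    return HarmonizedTable(
        out.loc[keep].copy(),
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        dropped=dropped,
    )
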
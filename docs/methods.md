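# Methods

## Model and assumptions

The package implements summary-data two-sample Mendelian randomization. A
variant is a valid instrument for an exposure if it is (i) associated with
the exposure, (ii) independent of exposure–outcome confounders, and (iii)
affects the outcome only through the exposure. Under these assumptions the
per-variant Wald ratio Γ/γ estimates the causal effect; the estimators
combine ratios under progressively weaker versions of (iii):

- **IVW** assumes all instruments valid (or balanced pleiotropy); it is the
  weighted regression of Γ on γ through the origin with weights 1/σ_y².
- **MR-Egger** allows directional pleiotropy under InSIDE (pleiotropy
  independent of instrument strength); its intercept estimates the average
  directional pleiotropy and its slope remains a consistent causal estimate.
- The **weighted median** is consistent when at least half of the weight is
  on valid instruments; the **mode-based estimators** when the largest
  homogeneous cluster of ratios is valid.

Binary outcomes are handled on the log-odds scale throughout; `exp(beta)` is
reported as an odds ratio with a 95% Wald interval using the conventional
1.96 quantile.

Two-step mediation estimates the exposure→mediator effect with the
exposure's instruments and the mediator→outcome effect with the mediator's
instruments, both by univariable IVW. The mediated effect is the product of
coefficients; its SE is the first-order delta method
√(β_xm²SE_my² + β_my²SE_xm²); the direct effect is defined as total −
mediated, so the decomposition is exact by construction. Step 2 is *not*
adjusted for the exposure (no multivariable MR); this mirrors the common
two-step design and is a known caveat — when exposure and mediator share
instruments the step-2 estimate absorbs the direct path. The screen excludes
mediators whose instrument set is indistinguishable from the exposure's for
this reason.

## Numerical and procedural choices

- **Wald-ratio SE** is the first-order delta approximation σ_y/|γ|, which
  ignores the exposure-side noise. Consequence: when the outcome GWAS is
  much better powered than the exposure GWAS, genuine exposure-side noise
  appears as heterogeneity and Cochran's Q can reject even without
  pleiotropy. This is the behaviour of the standard tooling and is left
  as-is; under the no-effect null the calibration is exact because the
  outcome noise is then the only noise in the ratios.
- **IVW random-effects** uses multiplicative SE inflation max(1, √(Q/(J−1)))
  — over-dispersion widens intervals, under-dispersion never narrows them.
  A fixed-effect variant is available by flag. Single-SNP IVW reduces to the
  Wald ratio.
- **MR-Egger** re-orients every instrument to the exposure-increasing allele
  before fitting, applies the same multiplicative over-dispersion rule to
  both coefficients, and reports two-sided normal p-values by default
  (t with J−2 df by flag) for cross-method consistency.
- **Median/mode SEs** come from a parametric bootstrap (1000 draws by
  default) that redraws both γ and Γ from normals with their reported SEs;
  fully seeded, bit-reproducible. Mode bandwidth is the modified Silverman
  rule 0.9·min(sd, MAD)·J^(−1/5) times a user factor (default 1), with the
  density evaluated on a 2048-point grid; coincident ratios are returned
  exactly.
- **Harmonization** aligns by allele labels (including reverse-complement
  matches) for unambiguous variants; palindromic A/T–C/G variants are
  oriented by allele-frequency inference with a drop window of EAF ∈
  [0.42, 0.58] (parameter), and dropped when either frequency is missing or
  uninformative. Window boundaries count as uninformative.
- **Clumping** is greedy by ascending p-value with lexicographic snp-id
  tie-breaks (deterministic output); pairs on different chromosomes or
  farther apart than the window (boundary inclusive) are never clumped.
  Instrument strength is computed on the exposure study, pre-harmonization,
  since the R² formula uses the exposure β, SE, EAF and N; rows lacking EAF
  are excluded from the strength filter with a warning.
- **MR-PRESSO** computes the observed residual sum of squares from
  leave-one-out IVW predictions and simulates its null by redrawing each
  Γ_j from N(γ_j·β_IVW(−j), σ_yj); p-values use the (1+#exceeding)/(n_sim+1)
  convention and can never be exactly zero. Outliers are flagged at a
  Bonferroni-adjusted per-SNP level; the distortion test compares the
  outlier-corrected IVW shift to shifts from removing random same-size SNP
  sets. Default n_sim = 1000.
- **Multiple testing**: the screens use nominal p < 0.05 as the primary
  significance rule, with a Benjamini–Hochberg column added to every screen
  table as a clearly supplementary adjustment.
- Per-pair bootstrap/PRESSO seeds are derived from the global seed and the
  trait labels (CRC32), making results invariant to the ordering of input
  collections.

## The synthetic generator

`simulate_study` draws summary statistics directly at the summary level (no
individual genotypes). Per SNP: MAF ~ U(0.05, 0.5); true SNP–exposure effect
γ ~ N(0, σ_γ²) with σ_γ = 0.06 by default; the GWAS standard error at sample
size n is 1/√(2n·MAF(1−MAF)); observed effects add independent normal noise
per study (non-overlapping samples). The mediator's genetic effects are
θ_xm·γ plus its own cis effects on dedicated SNPs; the outcome follows
Γ = θ_direct·γ + θ_my·(mediator effect) + α + δ, so θ_total = θ_direct +
θ_xm·θ_my by construction. Default structural coefficients encode the
headline decomposition studied here: θ_direct = 0.369, θ_xm·θ_my =
0.2 × 0.09 = 0.018, θ_total = 0.387 on the log-odds scale.

Default sample sizes follow the emulated sources: 18,340 (microbiome
consortium GWAS), 14,824 (circulating-protein pQTL study), 198,166 (disease case–control
GWAS). Mediator-specific effects default to σ_γ but the cis-pQTL regime uses
`mu_sd = 0.5` SD — circulating-protein cis signals are an order of magnitude
larger than microbiome trait effects, which is what makes protein
instruments usable at pQTL sample sizes.

Pleiotropy α is assigned to a configurable fraction of exposure SNPs:
`balanced` (mean zero), `directional` (positive mean, expressed relative to
the exposure-increasing allele — the orientation in which the Egger
intercept is defined — with the offset N(sd, (sd/2)²) dominating the
spread), or `inside_violating` (correlated with γ, ρ = 0.7). Disease-specific
SNPs δ provide reverse-MR instruments and feed back on the exposure with
coefficient θ_reverse (0 by default).

What the generator does **not** emulate: realistic human LD (LD fixtures are
mechanical block-diagonal matrices for exercising the clumping machinery,
not a genetic model), case–control ascertainment, winner's curse beyond what
selection on simulated p-values induces, sample overlap between studies, and
allele-frequency differences between cohorts. Passing tests therefore
demonstrate correctness of the estimators and machinery under the stated
model, not robustness to every artefact of real consortium data.

## Problem sizes for recovery and calibration runs

Parameter-recovery runs use 200 replicates of 100 instruments with a large
exposure GWAS (n = 2×10⁶) and cis-pQTL-scale mediator effects. This is the
strong-instrument regime: ratio estimators carry a finite-sample attenuation
of order SE_γ²/σ_γ² (regression dilution from noise in γ̂, a property of the
estimator, not the generator), and the large-n choice keeps that bias below
Monte-Carlo resolution so the runs measure estimator consistency rather than
the attenuation. Null-calibration runs use 500 replicates of 50 instruments
at the default sample sizes, where calibration is exact (see above). The
MR-PRESSO detection run uses 21 instruments with one 10-SE outlier across 20
seeds.

## Known limitations

- No multivariable MR: direct effects come from the difference
  decomposition, and step-2 mediation is univariable.
- No Steiger direction filtering, SIMEX-corrected Egger, or penalized IVW
  variants.
- No reference-panel LD: clumping requires a user-supplied (or synthetic)
  r² matrix.
- The proportion mediated is reported from unrounded effects; published
  roundings of the same arithmetic may differ in the last digit.
- The published 95% CI of a mediated effect cannot be reproduced from point
  estimates alone; `decompose_effects` therefore reports only the point
  decomposition, while `two_step_mediation` computes the delta-method CI
  from the step SEs.
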
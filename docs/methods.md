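# Methods

## The problem

α1-antitrypsin (AAT) is a metastable serpin whose disease-associated
variants (most importantly Z, E342K) misfold and polymerise via a
transiently sampled intermediate conformation. Methyl-TROSY NMR spectra of
protein variants show *collinear* chemical-shift perturbations (CSPs):
across many methyl groups, each variant's resonance sits a common fraction
of the way along the vector from the reference (wild-type, M) spectrum to
the spectrum of the ligand-bound state. This package turns such peak lists
into quantitative intermediate-state populations and free energies.

## Model and assumptions

**Fast two-state exchange.** Each methyl site has a native shift δ_N and
an intermediate shift δ_I. Exchange between N and I is fast on the
chemical-shift timescale, so one peak appears per site at the
population-weighted average δ_obs = (1−p_I)·δ_N + p_I·δ_I. The package
never fits lineshapes; fast exchange is assumed, and its self-consistency
is checked only through the timescale bound below.

**Bound state ≈ intermediate.** The ligand binds the intermediate with
high affinity and the bound spectra of different variants coincide, so the
bound-state shifts are used as a proxy for the (unbound) intermediate
shifts. This is an approximation, not an option: all population estimates
inherit it.

**Combined CSP.** Per-site differences are combined as
Δδ_CH = sqrt(Δδ_H² + (Δδ_C/4)²); the 1/4 weighting reflects the
gyromagnetic-ratio difference between ¹³C and ¹H and is used consistently
in the CSP tables, the transfer metric and the regression scaling.

**Collinear regression.** For each variant X, the 1H differences
(Δδ_H^{M→B}, Δδ_H^{M→X}) and the 0.25-scaled 13C differences enter a
pooled, unweighted regression through the origin. The slope
F_X = Σxy/Σx² is the fractional extent of the variant CSPs along the
free→bound axis; its standard error uses n−1 degrees of freedom
(one fitted parameter). Points are unweighted because the two nuclei are
treated as independent observations on the same scale after the 0.25
scaling; an optional |x| threshold can drop noise-dominated points but is
off by default. Orthogonal-distance regression is deliberately not used —
the x-axis (bound-state CSPs) is treated as the reference coordinate.

**Structural exclusion.** Methyls within an adjacency cutoff (default
8 Å, a typical methyl contact shell; configurable) of a mutation Cα or
any ligand atom report direct chemical perturbations rather than the
global equilibrium and are excluded from the regression. Mutation
adjacency takes precedence over ligand adjacency when both apply.
Sites missing from the structure are excluded as untraced.

**Conformational selection.** The scheme N ⇌ I ⇌ B (ligand binds only I)
gives two relations in normalised shift coordinates (reference variant at
F = 0, bound state at F = 1, native state at an offset φ_N ≤ 0):

    K_X = p_I/p_N = (F_X − φ_N)/(1 − F_X)
    Kd_app^X = (1 + K_X)/K_X · Kd

where Kd is the intrinsic affinity of the ligand for the pure
intermediate. The global fit minimises the weighted sum of squared
residuals of both relations over (φ_N, ln Kd, {ln K_X per variant}).
Profiling the per-variant ln K_X as explicit parameters keeps the
objective smooth and makes the noiseless fit exact; Kd residuals are
taken on the log scale because apparent affinities span orders of
magnitude across variants. Free energies use R = 1.9872×10⁻³
kcal mol⁻¹ K⁻¹ at T = 298 K with a 1 M standard state.

**Uncertainties.** Population and parameter errors come from a parametric
bootstrap (default 1000 resamples, seeded): fractions are resampled from
Gaussians with their standard errors, apparent Kds from lognormals with
their relative errors, and the model is refit. Noiseless inputs therefore
produce zero-width intervals. Bootstrap was preferred over covariance
linearisation because p_I = K/(1+K) is strongly nonlinear near the small
populations typical of the reference variant.

**Exchange timescale.** Fast exchange requires k_ex ≫ Δω = γB₀Δδ. The
bound is computed in angular units, Δω = 2π·ν₀·Δδ (rad/s), from the
largest observed ¹H shift difference; τ_ex < 1/Δω. A 0.4 ppm ¹H
difference at 900 MHz gives Δω ≈ 2250 rad/s and τ_ex ≪ 440 μs.

## Assignment transfer

Reference assignments are carried onto unassigned spectra in three tiers:
(1) mutual unique matches within (0.005, 0.02) ppm — a tight window of
order the digital resolution, chosen here since no value is standard;
(2) greedy one-to-one matching within ≤0.05 ppm ¹H and ≤0.1 ppm ¹³C,
smallest combined distance first, using a global priority queue so the
mapping is deterministic and order-independent (ties break by residue
number, then methyl label); (3) larger moves accepted only with
structural support — the site lies within the adjacency cutoff of a
declared mutation/ligand/glycosylation point or has spatial neighbours
(≤8 Å) already perturbed by ≥0.02 ppm combined — and, for Ile/Leu/Val,
a partner methyl whose perturbation agrees within a factor of 3
(floored at 0.005 ppm so ratios are not taken on pure noise). An
unmapped partner contributes its best-case displacement to any remaining
peak, which lets mutually perturbed methyl pairs bootstrap each other.
Stages 2–3 iterate (max 50 passes) until self-consistent. Peak
intensities are not used as a matching criterion: no quantitative rule
exists for them, only post-hoc validation.

The greedy global-queue strategy was validated against exhaustive
minimum-total-distance bipartite matching on small problems; on dense
spectra both strategies make the same unavoidable swaps when two peaks
sit closer together than the noise displacement.

## Synthetic data

The generator emulates: per-site native shifts drawn in realistic methyl
ranges (¹H −0.3 to 1.5 ppm; ¹³C per residue type at folded-protein
dispersion, e.g. Ile 8–19 ppm, Leu 20–27 ppm); intermediate perturbation
vectors with random orientation in (¹H, ¹³C/4) space and combined
magnitudes log-uniform in 0.01–0.3 ppm; per-variant populations
(defaults: reference ~2%, a Z-like variant at 27%, an S-like variant at a
0.4% relative extent, i.e. the fitted study conditions); Gaussian shift
noise (default σ_H = 0.005, σ_C = 0.02 ppm); and a declared subset of
sites placed inside the adjacency shell of a toy mutation point or ligand
atom, carrying deliberately non-collinear extra offsets so that the
exclusion logic is exercised, with all other sites kept outside both
shells. Apparent Kds, inhibition-stoichiometry curves, PFG diffusion
decays and TQ build-up curves are rendered from the same thermodynamic
parameters, so end-to-end recovery is a meaningful consistency check.

What the generator does **not** emulate: lineshapes and differential
relaxation (intensities are uniform), peak overlap beyond what the shift
distribution produces, glycoform doubling (except planted duplicates),
spectral artefacts, and any intermediate structure beyond a single
alternative shift per site. Passing recovery tests therefore demonstrates
correctness of the analysis under the stated model, not robustness to
every feature of experimental spectra.

## Ancillary assay fits

* **Stoichiometry of inhibition**: OLS line through (ratio, residual
  activity) points with activity > 0.05 (the floor avoids saturated
  points biasing the intercept); SI = −a/b with first-order error
  propagation from the OLS covariance.
* **Fluorescence polarisation**: the exact two-component quadratic
  isotherm f_b = (P+L+Kd − sqrt((P+L+Kd)² − 4PL))/(2L) fitted in
  (r_free, r_bound, ln Kd). The quadratic form matters because tight
  binders are titrated down to the probe concentration (ligand
  depletion); the unstated original fitting function is replaced by this
  explicit model.
* **Diffusion**: I(g) = I₀·exp(−D·γ²g²δ²(Δ−δ/3)) fitted nonlinearly with
  a linearised ln-slope start; gradients in G/cm are converted at
  1 G/cm = 0.01 T/m.
* **S²τc**: the TQ/SQ ratio build-up is fitted with a pluggable model,
  default 0.75·η·tanh(√(η²+δ²)T)/(√(η²+δ²) − δ·tanh(·)), whose rate η is
  converted to S²τc by the idealised-methyl dipolar constant
  (r_HH = 1.813 Å, methyl axis ⊥ H–H vector). Because no printed equation
  fixes this functional form, correctness is defined as self-consistency:
  data generated by the model are recovered exactly.

## Numerical choices and degenerate inputs

* Through-origin regression refuses all-zero x (no collinearity
  direction) and fewer than 3 shared non-excluded sites.
* The global fit refuses φ_N ≥ 1 (degenerate geometry) and K ≤ 0 in the
  apparent-Kd relation (no binding-competent population); shifts outside
  the [δ_N, δ_B] interval yield a negative K with a warning rather than
  an error, since noise can push a near-zero population slightly outside.
* Levenberg–Marquardt is used when residuals ≥ parameters, trust-region
  otherwise; fraction weights are floored (0.02) for noiseless inputs so
  the objective stays finite, while the bootstrap uses the true stated
  errors (zero noise → zero-width intervals).
* PDB parsing takes the first MODEL, altloc '' or 'A', heavy atoms only;
  distances are plain Euclidean in Å.
* Fixture determinism: every generator stream derives from a single
  scenario seed; regenerated scenario directories are byte-identical.

## Problem sizes

Default validation scenarios use 150 methyl sites (the assignment
coverage scale of a ~400-residue ILVMA-labelled protein), 3 variants,
10-seed repetition for recovery-rate properties, and 200–1000 bootstrap
resamples. These sizes make the full suite run in seconds while leaving
the statistical assertions well-powered.

## Known limitations

* Populations are per-variant, not per-site: the regression collapses all
  sites to one coordinate, so site-specific deviations from two-state
  behaviour are invisible (they only inflate the regression s.e.).
* The bound-state ≈ intermediate approximation biases populations if the
  ligand further perturbs the intermediate's shifts.
* The transfer algorithm cannot resolve genuinely ambiguous peaks (closer
  together than the noise displacement); such swaps are inherent to any
  shift-distance matcher without intensity or connectivity information.
* Kinetics (association/dissociation rates) are out of scope; only the
  fast-exchange lifetime bound is reported.
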
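# serpinmr

Quantifying transiently sampled conformational intermediates of
α1-antitrypsin (AAT) — and serpins like it — from methyl chemical-shift
perturbation (CSP) data.

Disease-linked AAT variants (Z, E342K; S, E264V) misfold and polymerise
through a sparsely populated intermediate state. In methyl-TROSY spectra
this intermediate betrays itself through *collinear* CSPs: under fast
two-state exchange every resonance sits at the population-weighted
average of the native (N) and intermediate (I) shifts, so a variant that
populates I more strongly moves all of its peaks a common fraction of the
way toward the spectrum of the intermediate — here approximated by the
state bound to a small-molecule polymerisation inhibitor that binds I by
conformational selection. `serpinmr` turns peak lists into that fraction,
and the fraction plus apparent binding affinities into populations and
free energies.

## The model

Per-site combined CSP (¹³C scaled by the gyromagnetic-ratio factor):

    Δδ_CH = sqrt(Δδ_H² + (Δδ_C/4)²)

Pooled regression through the origin of variant CSPs against free→bound
CSPs (¹H and 0.25-scaled ¹³C as independent points) gives the fractional
extent F_X per variant. With the reference variant at F = 0, the bound
state at F = 1 and the pure native state at an offset φ_N, the
conformational-selection scheme N ⇌ I ⇌ B gives

    K_X = p_I/p_N = (F_X − φ_N)/(1 − F_X)
    Kd_app^X = (1 + K_X)/K_X · Kd

which are fitted globally across variants for (φ_N, Kd, {K_X}), with
populations p_I = K_X/(1+K_X), free energies ΔG = −RT ln K_X and
bootstrap uncertainties. Supporting fits cover stoichiometry of
inhibition, fluorescence-polarisation titrations (exact quadratic
isotherm), Stejskal–Tanner diffusion and S²τc triple-quantum build-up.
See `docs/methods.md` for assumptions and numerical choices.

## Worked example

Generate a synthetic three-variant dataset at the study conditions
(150 methyl sites, reference ~2% intermediate, Z-like variant at 27%,
S-like at a 0.4% relative extent, shift noise σ_H = 0.005 / σ_C = 0.02
ppm, intrinsic Kd 15 nM) and run the full pipeline:

```
serpinmr synth --n-sites 150 --seed 1 --out demo
serpinmr run --config run.json      # states, structure, Kd table, seed
```

with `run.json` pointing at the rendered lists, the toy structure
(mutation residue 999, ligand residue LIG) and the rendered apparent-Kd
table. Output:

```
M: p_I = 0.0192 +/- 0.0014
Z: p_I = 0.2645 +/- 0.0064
S: p_I = 0.0231 +/- 0.0018
report written to demo_out/report.json
```

The Z-like variant's intermediate population is recovered at 26.5 ± 0.6%
against a generating value of 27%, the reference and S-like variants stay
at the few-percent level, and the report also contains the per-variant
collinear fractions (here Z: 0.2585 ± 0.0047 against a generating
relative extent of 0.2554), the fitted native-state offset
(φ_N = −0.008 ± 0.006), the intrinsic ligand affinity
(14.7 ± 0.8 nM against 15 nM) and the fast-exchange lifetime bound from
the largest ¹H shift difference (here Δω ≈ 1635 rad/s at 900 MHz, so
τ_ex < 0.61 ms). Exclusion lists (methyls within 8 Å of the mutation or
ligand site), thresholds and warnings are recorded in the report for
auditability.

Individual stages are available as `serpinmr transfer` (structure-guided
assignment transfer), `serpinmr csp`, `serpinmr collinear` and
`serpinmr fit`, or directly as library functions.

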
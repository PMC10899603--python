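# Methods

This note documents the models implemented in `indikit`, the defaults and
why, the numerical choices, what the synthetic-data generators do and do not
emulate, and known limitations.

## Consensus mutagenesis (`msa_consensus`)

**Model.** Given a gapped MSA containing the target ("reference") sequence,
homologs are first filtered by pairwise identity to the reference, computed
over columns where both sequences are non-gap (mutual-coverage convention;
`X` counts as missing), with a *strict* threshold (default > 0.60). Per-column
residue counts are then tallied **over homologs only** — the reference should
not vote for itself, so its row is excluded from all frequencies. A consensus
call at a reference position requires (i) homolog coverage ≥ `min_coverage`,
(ii) wildtype frequency ≤ `wt_max_freq`, and (iii) a modal non-gap residue
different from wildtype with frequency ≥ `consensus_min_freq`.

**Defaults.** `wt_max_freq = 0.30`, `consensus_min_freq = 0.50`,
`min_coverage = 0.70`. These are free parameters chosen so that a call
reflects a clear majority consensus against a genuinely under-represented
wildtype; all are CLI-overridable. Modal ties break by higher count, then
alphabetical order, making output deterministic. Reference numbering is
1-based ungapped, matching mutation nomenclature (E75P, …).

**Differential logo.** The exported matrix assigns each non-wildtype residue
its homolog frequency as a positive height and the wildtype residue the
negative deficit −(1 − f_wt). Frequency scaling (not information content) was
chosen as the more direct reading of "how often do homologs disagree here".
Rendering is left to external tools; the matrix is the contract.

**Active-site exclusion** removes calls whose Cα lies *strictly* within the
radius of any active-site Cα (so radius 0 is a no-op). Calls at positions
missing from the structure are retained, flagged, and warned about rather
than silently dropped.

**Out of scope.** MSA construction, phylogenetic weighting, ΔΔG prediction,
and the manual structural triage that a crystallographer would apply to the
automated call list.

## Structure screens (`structure_screen`)

**Disulfide scan.** Residue pairs (sequence separation ≥ 3 within a chain;
any interchain pair) pass a Cα–Cα ≤ 7.5 Å and 3.0 ≤ Cβ–Cβ ≤ 5.0 Å prefilter.
Sγ is modeled at 1.81 Å from Cβ with a tetrahedral Cα–Cβ–Sγ angle, scanning
χ1 on a 5° grid for both partners; the best grid point is polished by a local
Nelder–Mead refinement so that the accept decision is essentially independent
of grid resolution. A pair is accepted when some χ1 combination yields
|d(Sγ,Sγ) − 2.05 Å| ≤ 0.35 Å and |χ3| ∈ [60°, 120°]; the strain score
(Δd/0.35)² + ((|χ3|−87°)/30°)² is zero at ideal geometry and orders the
output. These windows are our own parameterization of the standard geometric
criteria family; no bit-parity with any particular published scanner is
intended. Glycine Cβ is reconstructed from N/Cα/C with ideal tetrahedral
geometry so Gly positions remain screenable; proline is excluded as a partner
(no mutable Cβ–H geometry, standard practice). Alternate locations resolve to
the highest-occupancy conformer; author numbering is preserved. Only chains
explicitly present in the input are scanned — no crystallographic symmetry
mates.

**Flexible segments.** Cα B-factors are z-normalized per chain (hence
invariant to affine rescaling of all B-factors), smoothed with a centered
sliding window (default 5 residues, full windows only — the smoothed value is
undefined at chain termini), and maximal runs above the z threshold (default
1.0) are merged into segments.

**Loop grafting.** Donor loops qualify when the 2 × n (default 3) anchor
Cα atoms flanking the loop superpose onto the target's with RMSD ≤ 1.0 Å
(Kabsch, proper rotation enforced) and the donor loop is *strictly* shorter.
Sorting is by (length delta, anchor RMSD). Kabsch rejects fewer than 3 points
or near-collinear sets, for which the rotation is not identifiable.

## Melt-curve analysis (`melt_analysis`)

**Model.** F(T) = base + amp/(1 + exp((Tm − T)/slope)), the two-state
(Boltzmann) unfolding sigmoid. The post-transition aggregation decay seen
near 99 °C in dye-based DSF is excluded by truncating the trace at its global
fluorescence maximum before fitting — standard practice for this assay type.
The fit is bounded least squares (Tm inside the data range, slope > 0) with
analytic initialization from the smoothed-derivative peak, so noiseless
curves refit exactly and the estimate is invariant under affine transforms of
the fluorescence. A smoothed derivative-maximum estimator is provided as an
independent cross-check; the two agree within 0.5 °C on clean sigmoids.

**Aggregation.** Replicates aggregate to mean ± SEM (sd/√n, n−1 denominator;
SEM is 0 and flagged for n = 1), and ΔTm is the mean minus the wildtype mean.
Mutation combination selects single-mutant records with ΔTm ≥ 1.0 °C and
retained activity ≥ 0.8 (both free parameters; records lacking activity data
pass by default), resolving positional conflicts by larger ΔTm.

**Not implemented.** Multi-transition unfolding models, dye photophysics,
and any conversion of ΔTm to an unfolding free energy (that mapping requires
calorimetric parameters outside this package's inputs).

## Reaction and photolysis kinetics (`reaction_kinetics`)

Calibration is ordinary least squares of peak area against concentration
(≥ 3 points, ≥ 2 distinct levels). Conversion is product over
stoichiometry-scaled substrate, reported even above 1 with a mass-balance
warning. The photolysis decay A(t) = A₀e^(−kt) is fit by *nonlinear* least
squares on the untransformed signal — log-linear regression would be biased
by noisy near-zero tails and is used only for initialization. Peak-area
signals are normalized to the t = 0 area first. Rates whose implied decay
over the observed span is below numerical noise are reported as exactly 0
(infinite half-life). The order comparison fits a floored linear decay as the
zero-order alternative and compares small-sample AICc values, declaring
"indeterminate" when fewer than six points remain or the AICc gap is under 2.
Times are hours throughout; substrate release by the coupled esterase is
treated as instantaneous.

## Techno-economics (`tea`)

**Scope.** Raw materials plus electricity only — no capital expenditure,
labor, depreciation, or utilities for the enzymatic steps; for the photolytic
process electricity is a raw material. This keeps processes at very different
technology-readiness levels comparable.

**Conventions.** Prices are USD/kg or USD/kWh. Aqueous buffer prices are per
kg of *prepared solution* with 1 L ≈ 1 kg, matching how bulk buffer prices
are quoted. The built-in price table (indoxyl 5, enzymes 25, UDP 50, sucrose
0.5, water 0.0077, electricity 0.12 USD/kWh, HEPES 246.5, citrate-phosphate
0.1, phosphate 0.059, HCl 0.06, caustic soda 4.5, sodium hydrosulphite 1.15,
Setamol 0.04, wetting agent 0.09) is editable via the YAML config. The cost
target is 60% (raw-material share) of 3× the 5 USD/kg incumbent selling
price, i.e. 9 USD/kg; a looser "<12 USD/kg" reading circulates alongside the
strict formula and the discrepancy is deliberately surfaced rather than
reconciled — `cost_target` implements the formula.

**Uncertainty.** Monte-Carlo propagation exploits the linearity of cost in
prices (amounts computed once, seeded draws per item; point / uniform /
triangular / lognormal families, defaults triangular with mode at the listed
price ± 50%). Breakeven uses plain bisection to 1e-6 relative tolerance and
requires the target to be bracketed.

**Market scale.** Defaults: 50,000 t/yr indigo demand, molar masses
262.3 / 295.3 g/mol, 2 mol indican per mol indigo, 65 mM batch titer, 100 m³
tanks, one batch per 2 days, 365 d/yr. "Every second day" is taken as
365/cycle_days = 182.5 batches/yr; the headline count is rounded to 2
significant figures (exact value ≈ 321), and the result is robust to the
182.5-vs-183 reading at that rounding.

**Presets.** `default_recipes()` ships two *illustrative synthetic*
compositions (a 1 L enzymatic glycosylation batch at 100 mM substrate / 65%
conversion, and a per-pair enzymatic dyeing bath). They are plausible
stand-ins for exploring the cost model, not measured mass balances, and no
published cost figure is asserted from them.

## Colorimetry (`colorimetry`)

Reflectance is resampled (linear interpolation, extrapolation forbidden) to a
5 nm grid over 400–700 nm — the range of the spectrophotometers this model
targets. Tristimulus values use Riemann Δλ summation with
k = 100/Σ S ȳ Δλ, so the perfect reflector has Y = 100 and maps to L\*a\*b\*
(100, 0, 0) *exactly by construction*, since Lab is always computed against
the white point of the embedded observer/illuminant pair. The CIE 1964 10°
color-matching functions are generated from the published multi-lobe Gaussian
analytic approximations (Wyman, Sloan & Shirley 2013, JCGT), accurate to a
few percent; D65 is the standard 10 nm relative-power tabulation interpolated
to 5 nm. Both the analytic CMFs and the 400–700 nm truncation (versus the
full 380–780 nm tables) are documented approximations: they shift absolute
a\*/b\* of strongly chromatic samples slightly but leave all
normalization-based identities exact and all qualitative orderings intact.
Sensor negatives clip to 0 and reflectance above 1 (fluorescent whitening) to
1.05, with warnings.

Swatch summaries are per-channel mean ± sample SD (n−1). Population
statistics use linear-interpolation percentiles, whiskers at the most extreme
points within 1.5 × IQR of the quartiles, and points beyond as outliers —
the convention of standard statistical plotting software. Color-difference
metrics (ΔE2000) and instrument-geometry corrections are out of scope.

## Synthetic data (`synthetic_data`)

All generators take a single integer seed into a local `numpy` Generator (no
global state), return in-memory objects, and — when writing files — serialize
the ground truth as a JSON sidecar; identical specs give byte-identical
output.

* **MSA**: 18 homologs at target identities drawn from [0.62, 0.95] around a
  random reference. At planted positions, exactly round(0.6·n) homologs carry
  the consensus residue and ⌊0.15·n⌋ keep wildtype, so the default calling
  thresholds are met with margin and recovery is exact by construction; the
  default planted set is the ten stabilizing sites of the engineered
  decatuple variant. Background mutations avoid planted columns. *Not*
  emulated: realistic substitution matrices, indels/gaps, phylogenetic
  correlation between homologs — so perfect planted-signal recovery says the
  caller implements its definition correctly, not that real alignments are
  this clean.
* **Structures**: poly-alanine on an idealized helical path; planted
  disulfide pairs are rebuilt at textbook geometry from the same internal-
  coordinate constants the scanner uses (hence recovered at ≈ 0 strain);
  B-factors are a 20 Å² baseline with a short-period ripple plus Gaussian
  bumps (peak +30) on hotspot ranges, defaulting to the two flexible loops of
  the target enzyme (residues 251–261 and 310–336). No crystallographic
  noise, occupancy disorder, or missing density is simulated.
* **Melt curves**: Boltzmann sigmoid + baseline + Gaussian noise (default 2%
  of amplitude) on a 25–99 °C grid, 3 replicates; the default variant pair is
  13.1 °C apart. No aggregation decay is added by default (the fitter's
  truncation is exercised separately).
* **Decays**: exponential with multiplicative Gaussian noise over 6 h.
* **Prices**: triangular distributions, mode at the listed price ± 50%, for
  enzymes, sucrose, and indoxyl by default.
* **Reflectance**: smooth template curves (denim blue with a 450 nm
  reflectance peak that guarantees b\* < 0 at any dye depth; flat 18% gray;
  warm undyed fabric) plus small additive noise. No fluorescence, gloss, or
  instrument-geometry effects.

## Problem sizes used in the checks

The automated checks run the consensus caller against exhaustive enumeration
on all 2-homolog × 2-column and 3-homolog × 1-column alignments over a
4-letter alphabet plus 500 random alignments up to 6 × 10 (full enumeration
of the 6 × 10 space is combinatorially impossible); the disulfide decision
against a 1° brute-force grid on 20 random pairs; Tm and rate recovery over
100 seeded simulations each; and Monte-Carlo convergence at 10⁵ draws. These
sizes give the comparisons sub-percent statistical resolution while keeping
the whole suite fast.

## Known limitations

* Consensus calling reproduces the automated part of variant design only;
  published campaigns additionally applied manual structural triage, so
  matching a published variant *count* is not a goal.
* The disulfide scan models Sγ from fixed ideal internal coordinates; no
  side-chain repacking or energy model backs the strain score.
* The TEA covers raw materials and electricity; absolute published cost
  figures that depend on full mass-and-energy balances are outside what the
  package can recompute.
* Lab values carry the few-percent CMF-approximation and truncation error
  described above; applications needing certified colorimetry should swap in
  measured tables (the conversion accepts explicit observer/illuminant
  arrays).
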
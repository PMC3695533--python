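# Methods

`quadstall` analyzes how an RNA G-quadruplex embedded in the open
reading frame of the human estrogen receptor α (hERα) mRNA behaves as a
thermodynamic unit, how that stability slows translation elongation,
and how the slow-down propagates to a cellular proteolysis phenotype.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic data do and do not establish.

## Two-state van't Hoff melting (`melt_thermo`)

The folding of an intramolecular quadruplex is modelled as a two-state
equilibrium with temperature-independent enthalpy:

    ΔG(T) = ΔH·(1 − T/Tm),   ΔS = ΔH/Tm,
    K(T) = exp(−ΔG/(R·T)),    f(T) = K/(1+K).

The observable melting curve is the population-weighted sum of two
linear baselines, A(T) = f·(a_f + b_f·T) + (1−f)·(a_u + b_u·T), and all
six parameters (ΔH, Tm, four baseline coefficients) are fitted jointly
by trust-region least squares. The two-state constraint ΔS = ΔH/Tm is
imposed through the (ΔH, Tm) parameterization rather than a penalty, so
ΔG(Tm) = 0 holds exactly by construction.

Constants: R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹; 37 °C ≡ 310.15 K; °C↔K
offset 273.15. Energies are kcal/mol throughout because that is the
unit of the reported stability table.

Numerical choices:

- **Initialization.** Tm starts at the extremum of the Savitzky–Golay
  smoothed derivative dA/dT (window 11, order 3); |ΔH| starts at
  4·R·Tm²·|df/dT| evaluated on the crudely normalized curve, clipped to
  [5, 200] kcal/mol. Three starts (derivative peak, ±5 °C) run before a
  fit is declared non-convergent.
- **No-transition rule.** The sigmoidal amplitude is the largest
  deviation of the smoothed curve from the chord joining its ends; the
  noise floor is estimated from second differences
  (median(|Δ²A|)/1.349/√6). Amplitude < 5× noise raises
  `NoTransitionError` — this is how a variant that never folds (the
  A-mutant analogue) surfaces as "ND" instead of a garbage fit.
- **Sign-agnostic amplitude.** Quadruplex melting monitored at 295 nm
  is hypochromic (signal falls on heating) but the fit accepts either
  sign, so CD-monitored curves (signal falls at 265 nm on melting) fit
  with the same code path.
- **Uncertainties.** Replicates are fitted independently and summarized
  as mean ± SD (ddof=1); the SD is reported only with ≥ 2 replicates.
  Single-fit covariance is deliberately not used: the study's own
  uncertainties are between-profile scatter over five melts.
- **Normalization** to folded fraction uses the fitted baselines and
  clips to [−0.05, 1.05]; clipping beyond that indicates baseline
  misfit and is the caller's signal to inspect.

Inverting a reported (ΔG°37, Tm) pair via ΔH = ΔG°37/(1 − 310.15/Tm_K)
determines the model completely; this is how the generator turns the
published table into forward-simulation parameters (wild-type
−45.69 kcal/mol, C −46.33, G −45.89, U −50.74).

The heating rate (0.2 °C/min) is carried as metadata but not modelled:
the analysis assumes equilibrium melting, as the slow ramp justifies.
No multi-state, intermolecular, or cosolute-correction models are
provided.

## CD two-state diagnostics (`cd_twostate`)

If melting is two-state, every spectrum in a temperature series is a
mixture f(T)·B_folded(λ) + (1−f(T))·B_unfolded(λ) of two basis spectra.
Two consequences are used as diagnostics:

- **Isosbestic point**: wherever the bases cross, the intensity is
  temperature-invariant. Implemented as the argmin over the wavelength
  grid of the cross-temperature variance of the raw intensity; ties
  (within 10⁻¹² of the profile maximum, to absorb float rounding)
  resolve to the lowest wavelength. With uniform instrument noise this
  variance criterion is only discriminating where the bases actually
  differ — on noisy series the argmin can land on any low-contrast
  wavelength, so the zero-spread property is asserted on exact series
  and the noisy behaviour is treated as qualitative ("near 250 nm").
- **Two-wavelength linearity**: intensities at any two wavelengths are
  affinely related across temperatures, so the Pearson r of the
  265 nm vs 242 nm trace is ±1 up to noise. Wavelengths match the
  nearest grid point within 1 nm, else error.

The parallel-topology call requires a positive maximum in 260–270 nm
and a negative minimum in 235–245 nm, both exceeding a threshold of
2 mdeg (configurable; no numeric cutoff exists in the literature being
modelled — 2 mdeg cleanly separates the synthetic folded signature,
~9 mdeg, from the non-folding variant's residual, < 2 mdeg).

CD-monitored melting at 265 nm is just a `MeltingCurve` handed to the
same van't Hoff fit, which ties "the CD transition corresponds to the
UV transition" to a testable Tm equality.

## Stall-escape kinetics (`stall_kinetics`)

The synchronized-translation assay releases halted ribosomes (species
H, a 29-residue product) at t = 0 and follows the stalled intermediate
I (elongation arrested ~2 codons upstream of the quadruplex) and the
full-length product F. The model is a two-path first-order scheme:

- fraction φ of mRNAs carry a folded quadruplex: H →(k_fast) I →(k) F;
- fraction 1−φ do not: H →(k_fast) F;

with the escape rate exponential in the folding free energy,

    k = k₀ · exp(α·ΔG°37/(R·T)),   ΔG°37 ≤ 0,

which encodes the assumption that the activation energy for the
ribosome to unwind the quadruplex is proportional to its thermodynamic
stability. All species fractions are closed-form exponential sums
(ensemble averages — gel band intensities are population measurements,
so no stochastic simulation is warranted), and H+I+F = 1 exactly.

Defaults, with rationale (no rate constants are published for this
system; the defaults are chosen so the model reproduces the observed
time ranges of the gels):

- k_fast = 1 s⁻¹: ordinary elongation traverses the ~40 codons to the
  stall site within seconds; enforced ≥ 10·k₀ so the stall is
  rate-limiting.
- k₀ = 0.03 s⁻¹, α = 0.5: gives the weak folder (ΔG°37 = −0.47) an
  escape half-life of ~30 s — intermediate visible at 20 s, gone by
  600 s — while the stable folders (−4.8 to −5.9) escape with
  half-lives of 10–40 min, so full-length product accumulates
  measurably across the 600-s window yet the stalled intermediate
  remains the dominant species. Larger α values make the stable
  variants' escape invisible within 600 s, contradicting the gradual
  full-length accumulation the assay shows, and incidentally make
  (k₀, α) unidentifiable because only one variant then carries rate
  information.
- φ = 1 for the three stable folders, 0.5 for the partially folding
  U-variant, 0 for the non-folding A-variant.
- T fixed at 310.15 K (the reactions run at 37 °C).

Fitting: (log k₀, α, one φ per variant) by bounded least squares on the
I and F trajectories, k_fast held fixed; the t = 0 lane (pure H by
construction of the restart) is dropped during lane normalization.
95% CIs for k₀ and α come from the Gauss–Newton covariance at the
optimum; on a ridge the intervals blow up (capped at e⁵⁰⁰-fold for k₀)
rather than erroring. Identifiability guards: ≥ 2 distinct ΔG°37
values and ≥ 3 time points per course.

The stall position (codon ~272 of the receptor, six nucleotides before
the quadruplex) is biological context, not a simulated quantity; no
codon-resolution elongation, tRNA effects, or no-go-decay branch is
modelled.

## Cleavage-ratio model (`cleavage_model`)

Cellular expression of the receptor (or GFP fusions) yields full-length
and cleaved bands; the endpoint is ρ = (cleaved/full) normalized to the
non-folding standard variant, plotted against x = −ΔG°37 ≥ 0. The
standard sits at (0, 1) by construction, so the default fit is the
anchored single exponential ρ(x) = exp(b·x), least-squares on the ratio
scale (the reported uncertainties are on ratios, not log-ratios), with
optional 1/SD weighting; an affine form c + a·exp(b·x) is available for
sensitivity analysis. Normalization is replicate-paired — each
replicate's ratio is divided by the same replicate's standard ratio —
which makes every ρ invariant to per-gel scale factors. The partially
folding U-variant enters at its measured ΔG°37 = −0.47 despite
incomplete folding in cellular buffer; that is a deliberate
simplification, consistent with how the stability covariate is used on
the x-axis.

## Synthetic data (`synthetic_data`)

The generator emulates, with explicit seeds:

- **Melting**: 20–95 °C in 0.5 °C steps, five replicates per variant at
  295 nm, additive Gaussian noise sd 0.002 absorbance on a 0.10
  transition amplitude with gently sloping linear baselines; the
  non-folding variant produces a baseline-only profile.
- **CD**: a folded basis with the parallel signature (+9 mdeg at
  265 nm, −5 mdeg at 240 nm) and an unfolded basis pinned to cross it
  at exactly 250 nm, mixed by the same f(T); Gaussian noise sd
  0.3 mdeg.
- **Stall gels**: H/I/F band intensities at 0/20/60/120/300/600 s,
  multiplicative log-normal noise (5%).
- **Cleavage gels**: triplicate full/cleaved pairs with ρ = exp(0.3·x)
  and 5% multiplicative noise.

One master seed spawns a fixed-index `SeedSequence` child per file, so
bundles are byte-identical for a given config, and changing the seed
changes noise only — the manifest of ground-truth parameters is
seed-invariant. What passing on these data shows: the estimators
recover the parameters of their own generating model under realistic
noise at the study's replicate counts. What it does not show: substance
behaviour absent from the forward models — sloped or curved CD
baselines, heating-rate hysteresis, aggregation, partial intramolecular
alternatives to the two-state assumption, gel-lane background
subtraction — none of which the synthetic instruments produce.

## Sequences (`seqkit`)

The five printed 69-nt antisense primers and the 49-nt first-step
template are bundled; sense QFP windows are their reverse complements,
transcribed to RNA. The reading frame of the windows is determined
programmatically as the unique frame in which all four mutants are
synonymous with wild-type, rather than hard-coded from a figure. The
QFP scanner reports runs of ≥ 4 G-tracts (maximal G-runs ≥ `min_tract`)
chained by loops of 1–7 nt, greedy left-to-right, maximal, and
non-overlapping, with 0-based half-open coordinates on the scanned
strand only; `min_tract` defaults to 2 (admitting mixed-tetrad
candidates such as the U-variant) with 3 as the strict setting that
separates wild-type from the A-variant. Extinction coefficients use the
Cantor–Warshaw–Shapiro nearest-neighbor table (as tabulated in Puglisi
& Tinoco, Methods Enzymol. 180:304, 1989); the table is an argument, so
any published alternative can be substituted. Peptide masses are
average (not monoisotopic) masses — residue table plus one water, plus
one hydrogen when protonated — matching MALDI-scale reporting. The
bundled receptor FASTA is the canonical 595-residue hERα sequence; its
full-length average mass (66.2 kDa) and the position of the
quadruplex-encoded peptide GEGRGEVG (codons 274–281) serve as internal
consistency checks in the tests. Note that the N-terminal fragment
ending right before the quadruplex-encoded residues (1–273) computes to
30.2 kDa; 30.0 kDa corresponds to residues 1–271. The package computes
masses from the sequence as given and does not adjust either number.

## Pipeline and problem sizes

`run_pipeline` executes melting fits (per variant, five replicates), CD
diagnostics, the stall fit and the cleavage fit, and serializes a
report whose JSON is byte-stable across reruns (sorted keys, no
timestamps, SHA-256 input hashes as provenance). A full default-noise
run takes a few seconds on one core. The test suite uses 151-point
melting grids, 31×91 CD grids, 20-seed noise studies for melting and
stall recovery and a 100-seed study for the cleavage exponent — sizes
chosen to make the Monte-Carlo summaries stable at interactive run
times.

## Known limitations

- The two-state enthalpy is temperature-independent (no ΔCp term).
- The isosbestic locator is a variance argmin, informative only where
  the basis spectra differ appreciably relative to noise.
- The stall model treats the pre-quadruplex elongation as a single
  first-order step; it cannot represent distributive pausing.
- The kinetic and cleavage exponents (α, b) are calibrated on synthetic
  data only; no published rate constants or fit coefficients exist for
  this system to compare against.
- The cleavage model takes band intensities as given; densitometry and
  background subtraction are upstream of this package.
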
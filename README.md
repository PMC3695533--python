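# quadstall

Quantitative analysis of an RNA G-quadruplex inside an open reading
frame: how stable it is, how hard it stalls the ribosome, and how that
shows up as proteolysis of the encoded protein.

The package is built around the hERα (human estrogen receptor α) case:
a quadruplex-forming-potential (QFP) sequence in the hinge-region codons
of the *hERα* mRNA folds into a parallel G-quadruplex, temporarily
stalls translation elongation just upstream, and — through perturbed
co-translational folding — makes the protein sensitive to cleavage in
cells, in proportion to the quadruplex's thermodynamic stability. It is
intended for people who work with UV melting curves, CD spectra and gel
band tables of this kind and want the full chain, from printed
oligonucleotide sequences to a fitted stability–phenotype exponent, as
tested, scriptable code.

## Models

**Melting thermodynamics** — intramolecular two-state van't Hoff:

    ΔG(T) = ΔH·(1 − T/Tm),  ΔS = ΔH/Tm,  f(T) = K/(1+K),  K = e^(−ΔG/RT)

fitted to raw melting curves together with linear folded/unfolded
baselines (6 parameters), reporting ΔH, Tm, ΔG°37 with replicate SDs.

**CD diagnostics** — for a two-state melt every spectrum is a mixture
of two basis spectra, so the series has an isosbestic point and
perfectly correlated intensities at any two wavelengths (|r| = 1 at
265/242 nm up to noise); both are computed, plus a parallel-topology
call from the +265/−240 nm signature.

**Stall kinetics** — first-order escape from the quadruplex stall with
rate exponential in stability,

    k = k₀·exp(α·ΔG°37/RT),

driving a closed-form H → I → F species model fitted to synchronized-
translation band time courses.

**Cleavage model** — cleaved/full-length ratios normalized to the
non-folding standard variant and fitted to ρ(x) = exp(b·x) against
x = −ΔG°37.

A synthetic-data module generates every input (melting CSVs, CD series,
stall and cleavage band tables) from explicit seeds with ground-truth
manifests, so the whole pipeline is testable end to end offline.

## Worked example

Generate a synthetic study at the published design (five melting
replicates per variant, 3 mM K⁺ + PEG200 stabilities, n = 3 cleavage
replicates) and run the full analysis:

```
$ quadstall synth --seed 42 --out demo_bundle
$ quadstall run --data-dir demo_bundle --out-dir demo_report
thermodynamic stabilities (van't Hoff, two-state):
    A-mutant:  no transition (ND)
    C-mutant:  dG37 = -4.79 +/- 0.24 kcal/mol,  Tm = 72.5 +/- 0.5 C  (n=5)
    G-mutant:  dG37 = -5.77 +/- 0.38 kcal/mol,  Tm = 82.9 +/- 2.0 C  (n=5)
    U-mutant:  dG37 = -0.51 +/- 0.10 kcal/mol,  Tm = 40.1 +/- 0.5 C  (n=5)
   wild-type:  dG37 = -5.08 +/- 0.21 kcal/mol,  Tm = 76.6 +/- 0.8 C  (n=5)
CD: isosbestic 292 nm (spread 0.049); 265/242 correlation r = -0.9669
stall escape: k0 = 0.03422 /s, alpha = 0.518
cleavage: rho(x) = exp(b x), b = 0.306 /(kcal/mol)
```

Reading the output: the four folding variants come back within a
replicate SD of their generating stabilities (wild-type −5.15 kcal/mol,
Tm 76.4 °C; the scatter mimics instrument noise at sd 0.002
absorbance), and the non-folding A-variant is correctly flagged as
having no transition rather than being force-fitted. The 265/242 nm
correlation of −0.97 is the two-state linearity degraded by 0.3 mdeg
CD noise (an exact two-state series gives |r| = 1; the noisy isosbestic
argmin is only indicative — see `docs/methods.md`). The stall and
cleavage fits recover the generating k₀ = 0.03 s⁻¹, α = 0.5 and
b = 0.3 (kcal/mol)⁻¹ within a few percent. `demo_report/report.json`
holds the same numbers with provenance hashes and refits
byte-identically on rerun.

Sequence-level operations work directly on the printed oligos:

```
$ quadstall seq scan-qfp GAUGGGGAGGGCAGGGGUGAAGUGGGGUCU --min-tract 3
[{"start": 3, "end": 27, "tracts": [[3,4],[8,3],[13,4],[23,4]],
  "loop_lengths": [1, 2, 6]}]
$ quadstall seq mass GEGRGEVG
759.77
$ quadstall seq ext-coef GGGGAGGGCAGGGGUGAAGUGGGG
260560
```

— the wild-type QFP window carries four G-tracts (the third inside
GGGC) with loops of 1, 2 and 6 nt; `mass` is the average peptide mass
in Da; `ext-coef` the nearest-neighbor ε₂₆₀ in L·mol⁻¹·cm⁻¹.

The same functionality is importable (`quadstall.melt_thermo.fit_two_state`,
`quadstall.stall_kinetics.fit_escape`, ...); the CLI is a thin layer.

## Layout

- `src/quadstall/seqkit.py` — sequences, synonymy, QFP scanner, ε₂₆₀,
  peptide masses, FASTA I/O (bundled: the printed primers, the
  canonical hERα protein)
- `src/quadstall/melt_thermo.py` — two-state forward model and fits
- `src/quadstall/cd_twostate.py` — CD diagnostics
- `src/quadstall/stall_kinetics.py` — escape-rate model and fits
- `src/quadstall/cleavage_model.py` — ratio normalization and
  exponential fit
- `src/quadstall/synthetic_data.py` — seeded instrument emulation
- `src/quadstall/pipeline.py`, `cli.py` — orchestration and the
  `quadstall` command

`docs/methods.md` documents the models, defaults and limitations.
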
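"""Synthetic instrument data with the statistical structure the analysis assumes.

Every input the pipeline consumes — UV melting profiles, CD spectral
series, synchronized-translation band intensities and cellular cleavage
band tables — is generated here from a single :class:`ScenarioConfig`,
so the full analysis is testable without instruments or downloads. The
default scenario reproduces the study design: five QFP variants whose
folded members have the reported (dG37, Tm) pairs, five melting
replicates per variant, a CD series with an exact isosbestic point at
250 nm, stall time courses sampled at 0/20/60/120/300/600 s, and
triplicate cleavage tables whose normalized ratios follow
rho = exp(b * (-dG37)) with multiplicative band noise.

Noise models: additive Gaussian on absorbance (sd 0.002) and CD
intensity (sd 0.3 mdeg); multiplicative log-normal (5%) on gel band
intensities, since densitometry error scales with the band.

Determinism: one master seed; every file draws from a sub-generator
spawned as ``SeedSequence([master_seed, stream_index])``, so outputs
are byte-identical for a given config and changing the seed changes
only the noise, never the ground truth recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cd_twostate, melt_thermo
from .melt_thermo import (Baselines, TwoStateParams, params_from_dG37_Tm,
                          simulate_curve, write_melting_csv)
from .stall_kinetics import StallModel, simulate_timecourse

__all__ = [
    "VariantSpec", "ScenarioConfig", "make_study_scenario",
    "generate_bundle", "folded_basis", "unfolded_basis",
]

REPORTED_STABILITIES = {
    # variant: (dG37 kcal/mol, Tm Celsius); the A-mutant never folds (ND)
    "wild-type": (-5.15, 76.4),
    "A-mutant": (None, None),
    "C-mutant": (-4.77, 72.6),
    "G-mutant": (-5.86, 82.4),
    "U-mutant": (-0.47, 39.9),
}

DEFAULT_PHI = {"wild-type": 1.0, "A-mutant": 0.0, "C-mutant": 1.0,
               "G-mutant": 1.0, "U-mutant": 0.5}


@dataclass(frozen=True)
class VariantSpec:
    """Ground truth for one QFP variant.

    ``dG37``/``Tm_celsius`` are None for a variant with no melting
    transition; ``phi`` is the folded-mRNA fraction used by the stall
    and cleavage simulations.
    """

    name: str
    dG37: float | None
    Tm_celsius: float | None
    phi: float

    @property
    def folds(self) -> bool:
        return self.dG37 is not None

    @property
    def params(self) -> TwoStateParams | None:
        if not self.folds:
            return None
        return params_from_dG37_Tm(self.dG37, self.Tm_celsius)


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete, self-contained description of one synthetic study."""

    variants: tuple[VariantSpec, ...]
    seed: int = 42
    # melting
    melt_T_start: float = 20.0
    melt_T_stop: float = 95.0
    melt_T_step: float = 0.5
    melt_noise_sd: float = 0.002
    melt_n_replicates: int = 5
    melt_wavelength: float = 295.0
    melt_amplitude: float = 0.10     # folded-minus-unfolded signal span
    # CD
    cd_T_start: float = 20.0
    cd_T_stop: float = 95.0
    cd_T_step: float = 2.5
    cd_wl_start: float = 220.0
    cd_wl_stop: float = 310.0
    cd_wl_step: float = 1.0
    cd_noise_sd: float = 0.3
    # stall kinetics
    stall_k0: float = 0.03
    stall_alpha: float = 0.5
    stall_k_fast: float = 1.0
    stall_times: tuple[float, ...] = (0.0, 20.0, 60.0, 120.0, 300.0, 600.0)
    stall_band_scale: float = 1000.0
    stall_noise_cv: float = 0.05
    # cleavage
    cleavage_b: float = 0.3
    cleavage_standard_ratio: float = 0.2
    cleavage_n_replicates: int = 3
    cleavage_band_scale: float = 1000.0
    cleavage_noise_cv: float = 0.05

    @property
    def melt_grid(self) -> np.ndarray:
        n = int(round((self.melt_T_stop - self.melt_T_start)
                      / self.melt_T_step)) + 1
        return self.melt_T_start + self.melt_T_step * np.arange(n)

    @property
    def cd_T_grid(self) -> np.ndarray:
        n = int(round((self.cd_T_stop - self.cd_T_start)
                      / self.cd_T_step)) + 1
        return self.cd_T_start + self.cd_T_step * np.arange(n)

    @property
    def cd_wl_grid(self) -> np.ndarray:
        n = int(round((self.cd_wl_stop - self.cd_wl_start)
                      / self.cd_wl_step)) + 1
        return self.cd_wl_start + self.cd_wl_step * np.arange(n)

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-stream generator spawned from the master seed."""
        return np.random.default_rng(np.random.SeedSequence(
            [int(self.seed), int(stream)]))


def make_study_scenario(seed: int = 42, noiseless: bool = False,
                         **overrides) -> ScenarioConfig:
    """The study scenario: reported stabilities, study replicate counts.

    ``noiseless=True`` zeroes every noise term (used for end-to-end
    self-consistency checks); other keyword overrides pass through to
    :class:`ScenarioConfig`.
    """
    variants = tuple(
        VariantSpec(name=name, dG37=dG, Tm_celsius=tm,
                    phi=DEFAULT_PHI[name])
        for name, (dG, tm) in REPORTED_STABILITIES.items()
    )
    if noiseless:
        overrides.setdefault("melt_noise_sd", 0.0)
        overrides.setdefault("cd_noise_sd", 0.0)
        overrides.setdefault("stall_noise_cv", 0.0)
        overrides.setdefault("cleavage_noise_cv", 0.0)
    return ScenarioConfig(variants=variants, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# CD basis spectra
#
# The folded basis carries the parallel-quadruplex signature (positive
# 265 nm band, negative 240 nm band); the unfolded basis is a damped
# copy plus a bump pinned so the two bases cross at exactly 250 nm,
# giving the series an exact isosbestic point there.

_ISOSBESTIC_NM = 250.0
_UNFOLDED_SCALE = 0.25


def folded_basis(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    return (9.0 * np.exp(-((wl - 265.0) ** 2) / (2 * 8.0 ** 2))
            - 5.0 * np.exp(-((wl - 240.0) ** 2) / (2 * 6.0 ** 2)))


def unfolded_basis(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    pin = folded_basis(np.array([_ISOSBESTIC_NM]))[0]
    bump = np.exp(-((wl - _ISOSBESTIC_NM) ** 2) / (2 * 20.0 ** 2))
    return (_UNFOLDED_SCALE * folded_basis(wl)
            + (1.0 - _UNFOLDED_SCALE) * pin * bump)


def _cd_series(config: ScenarioConfig, spec: VariantSpec,
               rng: np.random.Generator) -> cd_twostate.SpectrumSeries:
    wl = config.cd_wl_grid
    temps = config.cd_T_grid
    f = melt_thermo.fraction_folded(temps + melt_thermo.CELSIUS_OFFSET,
                                    spec.params)
    intensity = (f[:, None] * folded_basis(wl)[None, :]
                 + (1.0 - f)[:, None] * unfolded_basis(wl)[None, :])
    if config.cd_noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.cd_noise_sd,
                                           size=intensity.shape)
    return cd_twostate.SpectrumSeries(wavelengths=wl, temperatures=temps,
                                      intensity=intensity)


def _spectrum_37C(config: ScenarioConfig, spec: VariantSpec,
                  rng: np.random.Generator) -> np.ndarray:
    wl = config.cd_wl_grid
    if spec.folds:
        f37 = melt_thermo.fraction_folded(melt_thermo.T37_K, spec.params)
        spectrum = (f37 * folded_basis(wl)
                    + (1.0 - f37) * unfolded_basis(wl))
    else:
        # non-folding variant: weak residual signal below the call threshold
        spectrum = 0.8 * unfolded_basis(wl)
    if config.cd_noise_sd > 0:
        spectrum = spectrum + rng.normal(0.0, config.cd_noise_sd,
                                         size=spectrum.shape)
    return spectrum


# ---------------------------------------------------------------------------
# per-assay generators


def _melting_curves(config: ScenarioConfig, spec: VariantSpec,
                    stream: int) -> list[melt_thermo.MeltingCurve]:
    """Five replicate 295-nm profiles; flat baseline only if no transition."""
    grid = config.melt_grid
    # hypochromic transition: folded baseline above unfolded at 295 nm
    baselines = Baselines(a_folded=0.30 + config.melt_amplitude,
                          b_folded=-2e-4,
                          a_unfolded=0.30, b_unfolded=-1e-4)
    curves = []
    for r in range(config.melt_n_replicates):
        rng = config.rng(stream * 100 + r)
        rep = f"rep{r + 1}"
        if spec.folds:
            curve = simulate_curve(
                spec.params, baselines, grid,
                noise_sd=config.melt_noise_sd,
                seed=rng.integers(2 ** 31),
                wavelength=config.melt_wavelength, replicate_id=rep,
            )
        else:
            signal = baselines.unfolded(grid + melt_thermo.CELSIUS_OFFSET)
            if config.melt_noise_sd > 0:
                signal = signal + rng.normal(0.0, config.melt_noise_sd,
                                             size=signal.size)
            curve = melt_thermo.MeltingCurve(
                temperatures=grid, signal=signal,
                wavelength=config.melt_wavelength, replicate_id=rep,
            )
        curves.append(curve)
    return curves


def _stall_bands(config: ScenarioConfig) -> pd.DataFrame:
    rows = []
    rng = config.rng(7001)
    times = np.asarray(config.stall_times, dtype=float)
    for spec in config.variants:
        model = StallModel(k0=config.stall_k0, alpha=config.stall_alpha,
                           phi=spec.phi, k_fast=config.stall_k_fast)
        dG = spec.dG37 if spec.folds else 0.0
        tc = simulate_timecourse(model, dG, times)
        for band, fractions in (("H", tc.H), ("I", tc.I), ("F", tc.F)):
            for t, frac in zip(times, fractions):
                noise = (rng.lognormal(0.0, config.stall_noise_cv)
                         if config.stall_noise_cv > 0 else 1.0)
                rows.append({
                    "variant": spec.name,
                    "dG37_kcal_mol": dG,
                    "time_s": t,
                    "band": band,
                    "intensity": config.stall_band_scale * frac * noise,
                })
    return pd.DataFrame(rows)


def _cleavage_bands(config: ScenarioConfig) -> pd.DataFrame:
    rows = []
    rng = config.rng(8001)
    std_ratio = config.cleavage_standard_ratio
    for spec in config.variants:
        dG = spec.dG37 if spec.folds else 0.0
        rho_true = float(np.exp(config.cleavage_b * (-dG)))
        for r in range(config.cleavage_n_replicates):
            ln = (lambda: rng.lognormal(0.0, config.cleavage_noise_cv)
                  if config.cleavage_noise_cv > 0 else 1.0)
            full = config.cleavage_band_scale * ln()
            cleaved = full * std_ratio * rho_true * ln()
            rows.append({
                "variant": spec.name,
                "dG37_kcal_mol": dG,
                "replicate": f"rep{r + 1}",
                "intensity_full": full,
                "intensity_cleaved": cleaved,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle


def generate_bundle(config: ScenarioConfig, out_dir: str | Path) -> Path:
    """Write every input CSV plus a ground-truth manifest; returns out_dir.

    Files: ``melting_<variant>.csv`` (replicated 295-nm profiles),
    ``cd_series_wild-type.csv`` (temperature series),
    ``cd_spectra_37C.csv`` (one spectrum per variant),
    ``stall_bands.csv``, ``cleavage_bands.csv``, ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for i, spec in enumerate(config.variants):
        write_melting_csv(_melting_curves(config, spec, stream=10 + i),
                          out / f"melting_{spec.name}.csv")

    wt = next(s for s in config.variants if s.name == "wild-type")
    cd_twostate.write_spectrum_csv(
        _cd_series(config, wt, config.rng(6001)),
        out / "cd_series_wild-type.csv")

    spectra_rows = []
    for i, spec in enumerate(config.variants):
        spectrum = _spectrum_37C(config, spec, config.rng(6100 + i))
        for lam, val in zip(config.cd_wl_grid, spectrum):
            spectra_rows.append({"variant": spec.name, "wavelength_nm": lam,
                                 "intensity_mdeg": val})
    pd.DataFrame(spectra_rows).to_csv(out / "cd_spectra_37C.csv",
                                      index=False, float_format="%.10g")

    _stall_bands(config).to_csv(out / "stall_bands.csv", index=False,
                                float_format="%.10g")
    _cleavage_bands(config).to_csv(out / "cleavage_bands.csv", index=False,
                                   float_format="%.10g")

    manifest = {
        "config": dataclasses.asdict(config),
        "ground_truth": {
            "variants": {
                spec.name: {
                    "dG37_kcal_mol": spec.dG37,
                    "Tm_C": spec.Tm_celsius,
                    "dH_kcal_mol": (spec.params.dH if spec.folds else None),
                    "phi": spec.phi,
                }
                for spec in config.variants
            },
            "stall": {"k0_per_s": config.stall_k0,
                      "alpha": config.stall_alpha,
                      "k_fast_per_s": config.stall_k_fast},
            "cleavage": {"b_per_kcal_mol": config.cleavage_b},
            "cd_isosbestic_nm": _ISOSBESTIC_NM,
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
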
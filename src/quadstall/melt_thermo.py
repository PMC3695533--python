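"""Two-state van't Hoff analysis of intramolecular melting curves.

The folded/unfolded equilibrium of a unimolecular structure (here an RNA
G-quadruplex) is modelled as two-state with a temperature-independent
enthalpy:

    dG(T) = dH * (1 - T/Tm),      dS = dH/Tm
    K(T)  = exp(-dG(T) / (R T))
    f(T)  = K / (1 + K)                      (fraction folded)

The observable (absorbance at 295 nm, or CD intensity) is the
population-weighted sum of two linear baselines:

    A(T) = f(T) * (a_f + b_f T) + (1 - f(T)) * (a_u + b_u T)

Fitting the six parameters (dH, Tm, a_f, b_f, a_u, b_u) to a melting
curve yields the van't Hoff enthalpy, the melting temperature and the
folding free energy at 37 C (dG37). Energies in kcal/mol, temperatures
in Kelvin internally; curves are stored in Celsius as measured.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import savgol_filter
from scipy.special import expit

R_KCAL = 1.9872e-3        # gas constant, kcal mol^-1 K^-1
T37_K = 310.15            # 37 C in Kelvin
CELSIUS_OFFSET = 273.15

__all__ = [
    "R_KCAL", "T37_K", "CELSIUS_OFFSET",
    "MeltingCurve", "TwoStateParams", "Baselines", "TwoStateFit",
    "NoTransitionError", "FitConvergenceError",
    "fraction_folded", "dG_at", "params_from_dG37_Tm",
    "simulate_curve", "fit_two_state", "normalize_curve",
    "read_melting_csv", "write_melting_csv",
]


class NoTransitionError(ValueError):
    """The curve shows no resolvable folded-to-unfolded transition."""


class FitConvergenceError(RuntimeError):
    """All fit starts failed to converge; carries diagnostics."""


@dataclass(frozen=True)
class MeltingCurve:
    """A temperature-signal series from one melting experiment.

    ``temperatures`` in Celsius, strictly increasing, at least 20 points;
    ``signal`` is absorbance (dimensionless) or CD intensity (mdeg).
    ``heating_rate`` (C/min) is carried as metadata only — the analysis
    assumes equilibrium melting.
    """

    temperatures: np.ndarray
    signal: np.ndarray
    wavelength: float
    replicate_id: str = "r1"
    heating_rate: float = 0.2

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "signal", s)
        if t.size < 20:
            raise ValueError("melting curve needs at least 20 points")
        if t.size != s.size:
            raise ValueError("temperature and signal lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if not np.all(np.isfinite(s)):
            raise ValueError("signal contains non-finite values")

    @property
    def kelvin(self) -> np.ndarray:
        return self.temperatures + CELSIUS_OFFSET


@dataclass(frozen=True)
class TwoStateParams:
    """Van't Hoff parameters of one intramolecular transition.

    ``dH`` in kcal/mol (negative for a structure stable at low T),
    ``Tm`` in Kelvin. Entropy and dG37 follow from the two-state
    constraint dS = dH/Tm.
    """

    dH: float
    Tm: float

    def __post_init__(self) -> None:
        if self.Tm <= 0:
            raise ValueError("Tm must be positive (Kelvin)")

    @property
    def dS(self) -> float:
        """Entropy, kcal mol^-1 K^-1."""
        return self.dH / self.Tm

    @property
    def dG37(self) -> float:
        """Folding free energy at 37 C, kcal/mol."""
        return dG_at(T37_K, self)

    @property
    def Tm_celsius(self) -> float:
        return self.Tm - CELSIUS_OFFSET


@dataclass(frozen=True)
class Baselines:
    """Linear folded/unfolded baselines, signal = a + b * T(K)."""

    a_folded: float
    b_folded: float
    a_unfolded: float
    b_unfolded: float

    def folded(self, T_kelvin: np.ndarray) -> np.ndarray:
        return self.a_folded + self.b_folded * T_kelvin

    def unfolded(self, T_kelvin: np.ndarray) -> np.ndarray:
        return self.a_unfolded + self.b_unfolded * T_kelvin


@dataclass(frozen=True)
class TwoStateFit:
    """Result of fitting one curve or a replicate set.

    ``params``/``baselines``/``residual_rms`` describe the pooled or
    single fit; ``per_replicate`` holds the individual replicate fits and
    ``dG37_mean``/``dG37_sd`` etc. the replicate statistics (SD is None
    with fewer than two replicates, as a single profile carries no
    between-replicate scatter).
    """

    params: TwoStateParams
    baselines: Baselines
    residual_rms: float
    per_replicate: tuple["TwoStateFit", ...] = ()

    @property
    def dG37_mean(self) -> float:
        if self.per_replicate:
            return float(np.mean([f.params.dG37 for f in self.per_replicate]))
        return self.params.dG37

    @property
    def dG37_sd(self) -> float | None:
        return self._sd([f.params.dG37 for f in self.per_replicate])

    @property
    def Tm_mean_celsius(self) -> float:
        if self.per_replicate:
            return float(
                np.mean([f.params.Tm_celsius for f in self.per_replicate])
            )
        return self.params.Tm_celsius

    @property
    def Tm_sd_celsius(self) -> float | None:
        return self._sd([f.params.Tm_celsius for f in self.per_replicate])

    @staticmethod
    def _sd(values: list[float]) -> float | None:
        if len(values) < 2:
            return None
        return float(np.std(values, ddof=1))

    def to_dict(self) -> dict:
        out = {
            "dH_kcal_mol": self.params.dH,
            "dS_kcal_mol_K": self.params.dS,
            "Tm_K": self.params.Tm,
            "Tm_C": self.params.Tm_celsius,
            "dG37_kcal_mol": self.params.dG37,
            "baselines": dataclasses.asdict(self.baselines),
            "residual_rms": self.residual_rms,
            "n_replicates": len(self.per_replicate),
        }
        if self.per_replicate:
            out["dG37_mean_kcal_mol"] = self.dG37_mean
            out["dG37_sd_kcal_mol"] = self.dG37_sd
            out["Tm_mean_C"] = self.Tm_mean_celsius
            out["Tm_sd_C"] = self.Tm_sd_celsius
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# closed-form thermodynamics


def dG_at(T: float, params: TwoStateParams) -> float:
    """Free energy of folding at temperature T (Kelvin), kcal/mol.

    dG(T) = dH * (1 - T/Tm); exactly zero at T = Tm.
    """
    if T <= 0:
        raise ValueError("T must be positive (Kelvin)")
    return params.dH * (1.0 - T / params.Tm)


def fraction_folded(T, params: TwoStateParams):
    """Equilibrium folded fraction at T (Kelvin); f(Tm) = 1/2."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("T must be positive (Kelvin)")
    dG = params.dH * (1.0 - T / params.Tm)
    # K/(1+K) with K = exp(-dG/RT) is the logistic of -dG/RT
    out = expit(-dG / (R_KCAL * T))
    return float(out) if out.ndim == 0 else out


def params_from_dG37_Tm(dG37: float, Tm_celsius: float) -> TwoStateParams:
    """Invert the reported (dG37, Tm) pair to van't Hoff parameters.

    dH = dG37 / (1 - 310.15/Tm_K); the two printed quantities determine
    the two-state model completely.
    """
    Tm_K = Tm_celsius + CELSIUS_OFFSET
    if abs(Tm_K - T37_K) < 1e-9:
        raise ValueError("Tm = 37 C leaves dH undetermined")
    return TwoStateParams(dH=dG37 / (1.0 - T37_K / Tm_K), Tm=Tm_K)


# ---------------------------------------------------------------------------
# forward model and simulation


def _forward(T_kelvin: np.ndarray, params: TwoStateParams,
             baselines: Baselines) -> np.ndarray:
    f = fraction_folded(T_kelvin, params)
    return (f * baselines.folded(T_kelvin)
            + (1.0 - f) * baselines.unfolded(T_kelvin))


def simulate_curve(
    params: TwoStateParams,
    baselines: Baselines,
    T_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
    wavelength: float = 295.0,
    replicate_id: str = "r1",
) -> MeltingCurve:
    """Simulate one melting curve on a Celsius grid.

    Additive Gaussian noise of standard deviation ``noise_sd`` (signal
    units); deterministic for a given seed, exact forward model at
    noise_sd = 0.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.size == 0:
        raise ValueError("empty temperature grid")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    signal = _forward(T_grid + CELSIUS_OFFSET, params, baselines)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.size)
    return MeltingCurve(
        temperatures=T_grid, signal=signal, wavelength=wavelength,
        replicate_id=replicate_id,
    )


# ---------------------------------------------------------------------------
# fitting


def _initial_guess(curve: MeltingCurve) -> tuple[float, float, Baselines]:
    """Tm from the extremum of the smoothed derivative, dH from its slope."""
    T = curve.kelvin
    A = curve.signal
    window = min(11, A.size if A.size % 2 == 1 else A.size - 1)
    smooth = savgol_filter(A, window_length=window, polyorder=3)
    dAdT = np.gradient(smooth, T)
    i_tm = int(np.argmax(np.abs(dAdT)))
    Tm0 = float(T[i_tm])

    # crude baselines from the curve ends (10% tails)
    k = max(3, A.size // 10)
    b_f, a_f = np.polyfit(T[:k], smooth[:k], 1)
    b_u, a_u = np.polyfit(T[-k:], smooth[-k:], 1)
    baselines = Baselines(a_f, b_f, a_u, b_u)

    # normalized slope at the transition -> |dH| ~ 4 R Tm^2 |df/dT|
    amp = baselines.folded(np.array([Tm0]))[0] - baselines.unfolded(
        np.array([Tm0]))[0]
    if amp == 0:
        amp = smooth[0] - smooth[-1] or 1.0
    dfdT = dAdT[i_tm] / amp
    dH0 = -4.0 * R_KCAL * Tm0 ** 2 * abs(dfdT)
    dH0 = float(np.clip(dH0, -200.0, -5.0))
    return Tm0, dH0, baselines


def _estimate_noise(signal: np.ndarray) -> float:
    """Noise SD from second differences (robust to the smooth transition)."""
    if signal.size < 3:
        return 0.0
    return float(np.median(np.abs(np.diff(signal, 2))) / 1.349 / np.sqrt(6)
                 + 1e-12)


def _check_transition(curve: MeltingCurve) -> None:
    """Reject curves whose amplitude never rises above the noise floor.

    The transition amplitude is measured as the largest deviation of the
    smoothed curve from the straight line joining its ends; a flat or
    purely linear (baseline-only) profile fails with NoTransitionError,
    mirroring the "ND" outcome for a variant that never folds.
    """
    T = curve.kelvin
    A = curve.signal
    window = min(11, A.size if A.size % 2 == 1 else A.size - 1)
    smooth = savgol_filter(A, window_length=window, polyorder=3)
    chord = np.interp(T, [T[0], T[-1]], [smooth[0], smooth[-1]])
    amplitude = float(np.max(np.abs(smooth - chord)))
    noise = _estimate_noise(A)
    if amplitude < 5.0 * noise or amplitude < 1e-12:
        raise NoTransitionError(
            f"no transition: sigmoidal amplitude {amplitude:.3g} < 5 x "
            f"noise estimate {noise:.3g}"
        )


def _fit_single(curve: MeltingCurve) -> TwoStateFit:
    _check_transition(curve)
    T = curve.kelvin
    A = curve.signal
    Tm0, dH0, bl0 = _initial_guess(curve)

    def residuals(theta: np.ndarray) -> np.ndarray:
        dH, Tm, a_f, b_f, a_u, b_u = theta
        params = TwoStateParams(dH=dH, Tm=Tm)
        model = _forward(T, params, Baselines(a_f, b_f, a_u, b_u))
        return model - A

    lower = [-500.0, T[0] - 50.0, -np.inf, -np.inf, -np.inf, -np.inf]
    upper = [-0.1, T[-1] + 50.0, np.inf, np.inf, np.inf, np.inf]

    best = None
    failures = []
    for Tm_start in (Tm0, Tm0 - 5.0, Tm0 + 5.0):
        theta0 = np.array([
            dH0, np.clip(Tm_start, lower[1] + 1, upper[1] - 1),
            bl0.a_folded, bl0.b_folded, bl0.a_unfolded, bl0.b_unfolded,
        ])
        try:
            res = least_squares(residuals, theta0, bounds=(lower, upper),
                                method="trf", xtol=1e-14, ftol=1e-14,
                                gtol=1e-14)
        except Exception as exc:  # numerical failure of one start
            failures.append(f"start Tm={Tm_start:.1f}K: {exc}")
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitConvergenceError(
            "two-state fit failed from all starts: " + "; ".join(failures)
        )
    dH, Tm, a_f, b_f, a_u, b_u = best.x
    rms = float(np.sqrt(np.mean(best.fun ** 2)))
    return TwoStateFit(
        params=TwoStateParams(dH=float(dH), Tm=float(Tm)),
        baselines=Baselines(float(a_f), float(b_f), float(a_u), float(b_u)),
        residual_rms=rms,
    )


def fit_two_state(
    curves: MeltingCurve | Sequence[MeltingCurve],
) -> TwoStateFit:
    """Fit the two-state model to one curve or a replicate set.

    Each replicate is fitted independently (six parameters: dH, Tm and
    two linear baselines); the returned fit carries the replicate mean as
    its pooled parameters and the replicate SD as the uncertainty, the
    same aggregation the study applied to its five melting profiles.
    """
    if isinstance(curves, MeltingCurve):
        return _fit_single(curves)
    curves = list(curves)
    if not curves:
        raise ValueError("no curves given")
    if len(curves) == 1:
        return _fit_single(curves[0])
    fits = tuple(_fit_single(c) for c in curves)
    mean_params = TwoStateParams(
        dH=float(np.mean([f.params.dH for f in fits])),
        Tm=float(np.mean([f.params.Tm for f in fits])),
    )
    mean_baselines = Baselines(*[
        float(np.mean([getattr(f.baselines, name) for f in fits]))
        for name in ("a_folded", "b_folded", "a_unfolded", "b_unfolded")
    ])
    rms = float(np.mean([f.residual_rms for f in fits]))
    return TwoStateFit(params=mean_params, baselines=mean_baselines,
                       residual_rms=rms, per_replicate=fits)


def normalize_curve(curve: MeltingCurve, fit: TwoStateFit) -> MeltingCurve:
    """Rescale a curve to the folded fraction implied by fitted baselines.

    theta(T) = (A - unfolded(T)) / (folded(T) - unfolded(T)); values are
    clipped to [-0.05, 1.05] (clipping indicates baseline misfit and is
    reported via a warning attribute on the returned curve's replicate id
    staying unchanged — callers inspect the returned array directly).
    """
    T = curve.kelvin
    span = fit.baselines.folded(T) - fit.baselines.unfolded(T)
    if np.any(np.abs(span) < 1e-12):
        raise ValueError("degenerate baselines: folded == unfolded")
    theta = (curve.signal - fit.baselines.unfolded(T)) / span
    theta = np.clip(theta, -0.05, 1.05)
    return MeltingCurve(
        temperatures=curve.temperatures, signal=theta,
        wavelength=curve.wavelength, replicate_id=curve.replicate_id,
        heating_rate=curve.heating_rate,
    )


# ---------------------------------------------------------------------------
# CSV I/O (columns: temperature_C, signal, wavelength_nm, replicate)


def write_melting_csv(curves: Sequence[MeltingCurve],
                      path: str | Path) -> None:
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "temperature_C": c.temperatures,
            "signal": c.signal,
            "wavelength_nm": c.wavelength,
            "replicate": c.replicate_id,
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.10g")


def read_melting_csv(path: str | Path,
                     wavelength: float | None = None) -> list[MeltingCurve]:
    """Read melting curves, one per (wavelength, replicate) pair."""
    df = pd.read_csv(path)
    required = {"temperature_C", "signal", "wavelength_nm", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if wavelength is not None:
        df = df[df["wavelength_nm"] == wavelength]
        if df.empty:
            raise ValueError(f"{path}: no rows at {wavelength} nm")
    curves = []
    for (wl, rep), grp in df.groupby(["wavelength_nm", "replicate"],
                                     sort=True):
        grp = grp.sort_values("temperature_C")
        curves.append(MeltingCurve(
            temperatures=grp["temperature_C"].to_numpy(),
            signal=grp["signal"].to_numpy(),
            wavelength=float(wl), replicate_id=str(rep),
        ))
    return curves
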
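"""First-order kinetics of ribosome escape from a quadruplex stall.

The synchronized-translation experiment releases artificially halted
ribosomes at t = 0 and follows three gel species: H (the halted
29-residue product), I (the product stalled just upstream of the
quadruplex) and F (the full-length product). The model:

* a fraction ``phi`` of mRNA molecules carry a folded quadruplex; on
  those, elongation proceeds quickly (rate ``k_fast``) to the stall
  site (H -> I) and then escapes slowly (I -> F) with rate ``k``;
* the remaining ``1 - phi`` elongate straight through (H -> F at
  ``k_fast``).

Assuming the activation energy for escape is proportional to the
quadruplex folding stability, the escape rate is a single exponential
in the free energy:

    k = k0 * exp(alpha * dG37 / (R T))

with dG37 <= 0, so more stable structures (more negative dG37) give
exponentially slower escape; dG37 = 0 (no quadruplex) recovers k0.
All species fractions are closed-form sums of exponentials and conserve
mass exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .melt_thermo import R_KCAL, T37_K

__all__ = [
    "StallModel", "TimeCourse", "EscapeFit",
    "escape_rate", "simulate_timecourse", "fit_escape",
    "fractions_from_bands", "ASSAY_SAMPLE_TIMES",
]

# sampling times (s) of the synchronized-translation gels
ASSAY_SAMPLE_TIMES = (20.0, 60.0, 120.0, 300.0, 600.0)


@dataclass(frozen=True)
class StallModel:
    """Kinetic parameters of one stalling reaction.

    k0 : s^-1
        Escape rate in the absence of a quadruplex (dG37 = 0).
    alpha : dimensionless
        Proportionality of the activation energy to |dG37|.
    phi : fraction
        Fraction of mRNA molecules carrying a folded quadruplex.
    k_fast : s^-1
        Effective elongation rate of the unobstructed path; must exceed
        10 * k0 so the stall, not ordinary elongation, is rate-limiting.
    T : K
        Reaction temperature (the assays run at 37 C).
    """

    k0: float = 0.03
    alpha: float = 0.5
    phi: float = 1.0
    k_fast: float = 1.0
    T: float = T37_K

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if self.k_fast < 10.0 * self.k0:
            raise ValueError("k_fast must be >= 10 * k0")


@dataclass(frozen=True)
class TimeCourse:
    """Species fractions H, I, F over time; mass conserved exactly."""

    times: np.ndarray
    H: np.ndarray
    I: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "H", "I", "F"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        n = self.times.size
        if any(arr.size != n for arr in (self.H, self.I, self.F)):
            raise ValueError("species arrays must match times")
        total = self.H + self.I + self.F
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("H + I + F must equal 1 at every time")
        for name in ("H", "I", "F"):
            arr = getattr(self, name)
            if np.any(arr < -1e-12) or np.any(arr > 1.0 + 1e-12):
                raise ValueError(f"{name} outside [0, 1]")


@dataclass(frozen=True)
class EscapeFit:
    """Result of fitting the escape model to a set of time courses."""

    k0: float
    alpha: float
    phi: dict[str, float]
    k_fast: float
    T: float
    residual_rms: float
    k0_ci: tuple[float, float]
    alpha_ci: tuple[float, float]

    @property
    def model(self) -> StallModel:
        """A StallModel with the fitted rate constants (phi = 1)."""
        return StallModel(k0=self.k0, alpha=self.alpha, phi=1.0,
                          k_fast=self.k_fast, T=self.T)


def escape_rate(dG37: float, model: StallModel,
                T: float | None = None) -> float:
    """Stall-escape rate (s^-1) for a quadruplex of stability dG37.

    k = k0 * exp(alpha * dG37 / (R T)); dG37 = 0 encodes "no
    quadruplex" and returns k0 exactly.
    """
    if dG37 > 0:
        raise ValueError("dG37 must be <= 0 (0 encodes no quadruplex)")
    T = model.T if T is None else T
    return model.k0 * float(np.exp(model.alpha * dG37 / (R_KCAL * T)))


def _species_fractions(times: np.ndarray, phi: float, k_fast: float,
                       k: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form H, I, F for the two-path first-order scheme."""
    t = np.asarray(times, dtype=float)
    H = np.exp(-k_fast * t)
    if abs(k_fast - k) < 1e-12 * k_fast:
        through = k_fast * t * np.exp(-k_fast * t)
    else:
        through = (k_fast / (k_fast - k)) * (np.exp(-k * t)
                                             - np.exp(-k_fast * t))
    I = phi * through
    F = 1.0 - H - I
    return H, I, F


def simulate_timecourse(
    model: StallModel,
    dG37: float,
    sample_times: Sequence[float] = ASSAY_SAMPLE_TIMES,
) -> TimeCourse:
    """Deterministic species fractions at the requested times.

    At t = 0 all mass sits in H (the pre-incubated halted complex); the
    stalled path drains H through I to F, the unstalled path directly to
    F. Ensemble-average kinetics — band intensities on a gel report
    molecule populations, so no stochastic simulation is needed.
    """
    t = np.asarray(sample_times, dtype=float)
    if t.size == 0:
        raise ValueError("no sample times")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be >= 0 and increasing")
    k = escape_rate(dG37, model)
    H, I, F = _species_fractions(t, model.phi, model.k_fast, k)
    return TimeCourse(times=t, H=H, I=I, F=F)


def fractions_from_bands(df: pd.DataFrame) -> list[tuple]:
    """Lane-normalized species fractions from a band-intensity table.

    Expects columns ``variant, dG37_kcal_mol, time_s, band, intensity``
    with bands H/I/F; each lane (variant, time) is normalized by its
    total intensity. The t = 0 lane (all halted product, by design of
    the synchronized restart) is dropped since it carries no kinetic
    information. Returns ``(label, dG37, times, I_frac, F_frac)`` tuples
    ready for :func:`fit_escape`.
    """
    required = {"variant", "dG37_kcal_mol", "time_s", "band", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"band table missing columns {sorted(missing)}")
    entries = []
    for (variant, dG37), grp in df.groupby(["variant", "dG37_kcal_mol"],
                                           sort=True):
        lanes = grp.pivot_table(index="time_s", columns="band",
                                values="intensity").sort_index()
        fractions = lanes.div(lanes.sum(axis=1), axis=0)
        times = fractions.index.to_numpy(dtype=float)
        keep = times > 0
        entries.append((str(variant), float(dG37), times[keep],
                        fractions["I"].to_numpy()[keep],
                        fractions["F"].to_numpy()[keep]))
    return entries


def fit_escape(
    timecourses: Sequence[tuple],
    k_fast: float = 1.0,
    T: float = T37_K,
) -> EscapeFit:
    """Fit (k0, alpha, per-variant phi) to observed I/F trajectories.

    ``timecourses`` is a sequence of ``(label, dG37, times, I_obs,
    F_obs)`` tuples or ``(label, dG37, TimeCourse)``; observations may be
    noisy fractions (they need not conserve mass — only I and F enter
    the residuals, H being fixed by the fast first step). ``k_fast`` is
    held at its known value. 95% confidence intervals for k0 and alpha
    come from the Gauss-Newton covariance at the optimum.
    """
    parsed = []
    for entry in timecourses:
        if len(entry) == 3 and isinstance(entry[2], TimeCourse):
            label, dG37, tc = entry
            parsed.append((str(label), float(dG37), tc.times, tc.I, tc.F))
        else:
            label, dG37, times, I_obs, F_obs = entry
            parsed.append((str(label), float(dG37),
                           np.asarray(times, float),
                           np.asarray(I_obs, float),
                           np.asarray(F_obs, float)))
    if len({dG for _, dG, *_ in parsed}) < 2:
        raise ValueError("need >= 2 distinct dG37 values to identify alpha")
    for label, _, times, *_ in parsed:
        if times.size < 3:
            raise ValueError(
                f"{label!r}: >= 3 time points needed for identifiability"
            )

    labels = [p[0] for p in parsed]

    def unpack(theta):
        log_k0, alpha = theta[0], theta[1]
        phis = theta[2:]
        return np.exp(log_k0), alpha, phis

    def residuals(theta):
        k0, alpha, phis = unpack(theta)
        res = []
        for (label, dG37, times, I_obs, F_obs), phi in zip(parsed, phis):
            k = k0 * np.exp(alpha * dG37 / (R_KCAL * T))
            _, I_model, F_model = _species_fractions(times, phi, k_fast, k)
            res.append(I_model - I_obs)
            res.append(F_model - F_obs)
        return np.concatenate(res)

    theta0 = np.concatenate([[np.log(k_fast / 50.0), 0.5],
                             np.full(len(parsed), 0.5)])
    lower = np.concatenate([[np.log(1e-10), 0.0],
                            np.zeros(len(parsed))])
    upper = np.concatenate([[np.log(k_fast / 10.0), 50.0],
                            np.ones(len(parsed))])
    res = least_squares(residuals, theta0, bounds=(lower, upper),
                        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    k0, alpha, phis = unpack(res.x)

    # Gauss-Newton covariance; singular directions give infinite CIs
    m, p = res.fun.size, res.x.size
    dof = max(m - p, 1)
    s2 = 2.0 * res.cost / dof
    JTJ = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(JTJ) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    # se[0] is on log k0; cap the half-width so a ridge gives a huge
    # finite interval instead of an overflow
    half = min(1.96 * se[0], 500.0)
    k0_ci = (k0 * float(np.exp(-half)), k0 * float(np.exp(half)))
    alpha_ci = (float(alpha - 1.96 * se[1]), float(alpha + 1.96 * se[1]))
    return EscapeFit(
        k0=float(k0), alpha=float(alpha),
        phi={label: float(phi) for label, phi in zip(labels, phis)},
        k_fast=k_fast, T=T,
        residual_rms=float(np.sqrt(np.mean(res.fun ** 2))),
        k0_ci=k0_ci, alpha_ci=alpha_ci,
    )
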
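"""End-to-end analysis: melting fits, CD diagnostics, kinetics, cleavage.

Consumes a bundle directory (as produced by
:func:`quadstall.synthetic_data.generate_bundle` or assembled from real
instrument exports in the same CSV schemas) and emits a consolidated
report: a per-variant thermodynamic table (the study's stability-table
analogue), CD two-state diagnostics, the fitted stall-escape model and
the exponential cleavage fit. The report is deterministic for given
inputs — rerunning on the same bundle reproduces it byte-identically —
and every stage failure is recorded as a flag rather than silently
dropped; only a missing input file aborts the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cd_twostate import (isosbestic_point, melting_curve_at,
                          read_spectrum_csv, topology_signature,
                          two_state_linearity)
from .cleavage_model import (fit_exponential, read_cleavage_csv,
                             relative_ratios)
from .melt_thermo import (FitConvergenceError, NoTransitionError,
                          fit_two_state, read_melting_csv)
from .stall_kinetics import fit_escape, fractions_from_bands

logger = logging.getLogger("quadstall.pipeline")

REPORT_SCHEMA_VERSION = 1

__all__ = ["RunReport", "run_pipeline"]


@dataclass
class RunReport:
    """Consolidated results of one pipeline run."""

    melting: dict = field(default_factory=dict)
    cd: dict = field(default_factory=dict)
    stall: dict = field(default_factory=dict)
    cleavage: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "melting": self.melting,
            "cd": self.cd,
            "stall": self.stall,
            "cleavage": self.cleavage,
            "provenance": self.provenance,
            "failures": self.failures,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def summary(self) -> str:
        """Human-readable digest of the run."""
        lines = ["thermodynamic stabilities (van't Hoff, two-state):"]
        for name, res in self.melting.items():
            if res.get("no_transition"):
                lines.append(f"  {name:>10}:  no transition (ND)")
            else:
                dg_sd = res.get("dG37_sd_kcal_mol")
                tm_sd = res.get("Tm_sd_C")
                sd_dg = f" +/- {dg_sd:.2f}" if dg_sd is not None else ""
                sd_tm = f" +/- {tm_sd:.1f}" if tm_sd is not None else ""
                lines.append(
                    f"  {name:>10}:  dG37 = {res['dG37_mean_kcal_mol']:.2f}"
                    f"{sd_dg} kcal/mol,  Tm = {res['Tm_mean_C']:.1f}"
                    f"{sd_tm} C  (n={res['n_replicates']})"
                )
        if self.cd:
            iso = self.cd.get("isosbestic", {})
            lin = self.cd.get("linearity", {})
            lines.append(
                f"CD: isosbestic {iso.get('wavelength_nm', float('nan')):.0f}"
                f" nm (spread {iso.get('spread', float('nan')):.3g}); "
                f"265/242 correlation r = {lin.get('r', float('nan')):.4f}"
            )
        if self.stall:
            lines.append(
                f"stall escape: k0 = {self.stall['k0_per_s']:.4g} /s, "
                f"alpha = {self.stall['alpha']:.3f}"
            )
        if self.cleavage:
            lines.append(
                f"cleavage: rho(x) = exp(b x), "
                f"b = {self.cleavage['b_per_kcal_mol']:.3f} /(kcal/mol)"
            )
        if self.failures:
            lines.append("failures: " + "; ".join(self.failures))
        return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _melting_stage(data_dir: Path, report: RunReport) -> None:
    files = sorted(data_dir.glob("melting_*.csv"))
    if not files:
        raise FileNotFoundError(f"no melting_*.csv in {data_dir}")
    for path in files:
        variant = path.stem.removeprefix("melting_")
        curves = read_melting_csv(path)
        try:
            fit = fit_two_state(curves)
        except NoTransitionError as exc:
            logger.info("%s: %s", variant, exc)
            report.melting[variant] = {"no_transition": True,
                                       "detail": str(exc)}
            continue
        except FitConvergenceError as exc:
            report.melting[variant] = {"fit_failed": True,
                                       "detail": str(exc)}
            report.failures.append(f"melting:{variant}")
            continue
        entry = fit.to_dict()
        entry.setdefault("dG37_mean_kcal_mol", fit.dG37_mean)
        entry.setdefault("Tm_mean_C", fit.Tm_mean_celsius)
        entry["no_transition"] = False
        report.melting[variant] = entry
        logger.info("%s: dG37 %.3f kcal/mol, Tm %.2f C, rms %.2e",
                    variant, fit.dG37_mean, fit.Tm_mean_celsius,
                    fit.residual_rms)


def _cd_stage(data_dir: Path, report: RunReport) -> None:
    series_path = data_dir / "cd_series_wild-type.csv"
    if series_path.exists():
        series = read_spectrum_csv(series_path)
        iso = isosbestic_point(series)
        lin = two_state_linearity(series)
        report.cd["isosbestic"] = {"wavelength_nm": iso.wavelength,
                                   "spread": iso.spread}
        report.cd["linearity"] = {"r": lin.r, "slope": lin.slope,
                                  "intercept": lin.intercept}
        try:
            cd_fit = fit_two_state(melting_curve_at(series, 265.0))
            report.cd["melting_265nm"] = {
                "Tm_C": cd_fit.params.Tm_celsius,
                "dG37_kcal_mol": cd_fit.params.dG37,
            }
        except (NoTransitionError, FitConvergenceError) as exc:
            report.cd["melting_265nm"] = {"fit_failed": True,
                                          "detail": str(exc)}
            report.failures.append("cd:melting_265nm")
    spectra_path = data_dir / "cd_spectra_37C.csv"
    if spectra_path.exists():
        df = pd.read_csv(spectra_path)
        calls = {}
        for variant, grp in df.groupby("variant", sort=True):
            grp = grp.sort_values("wavelength_nm")
            call = topology_signature(grp["wavelength_nm"].to_numpy(),
                                      grp["intensity_mdeg"].to_numpy())
            calls[str(variant)] = {
                "classification": call.classification,
                "peak_nm": call.peak_wavelength,
                "peak_mdeg": call.peak_intensity,
                "trough_nm": call.trough_wavelength,
                "trough_mdeg": call.trough_intensity,
            }
        report.cd["topology"] = calls


def _stall_stage(data_dir: Path, report: RunReport,
                 k_fast: float) -> None:
    path = data_dir / "stall_bands.csv"
    if not path.exists():
        return
    entries = fractions_from_bands(pd.read_csv(path))
    try:
        fit = fit_escape(entries, k_fast=k_fast)
    except ValueError as exc:
        report.stall = {"fit_failed": True, "detail": str(exc)}
        report.failures.append("stall")
        return
    report.stall = {
        "k0_per_s": fit.k0,
        "alpha": fit.alpha,
        "phi": fit.phi,
        "k_fast_per_s": fit.k_fast,
        "k0_ci95_per_s": list(fit.k0_ci),
        "alpha_ci95": list(fit.alpha_ci),
        "residual_rms": fit.residual_rms,
    }


def _cleavage_stage(data_dir: Path, report: RunReport) -> None:
    path = data_dir / "cleavage_bands.csv"
    if not path.exists():
        return
    table = read_cleavage_csv(path)
    summaries = relative_ratios(table)
    x = np.array([s.x for s in summaries])
    rho = np.array([s.rho_mean for s in summaries])
    fit = fit_exponential(x, rho)
    report.cleavage = {
        "b_per_kcal_mol": fit.b,
        "form": fit.form_id,
        "residual_rms": fit.residual_rms,
        "ratios": {
            s.variant: {"x": s.x, "rho_mean": s.rho_mean,
                        "rho_sd": s.rho_sd, "n": s.n_replicates}
            for s in summaries
        },
    }


def run_pipeline(
    data_dir: str | Path,
    out_dir: str | Path | None = None,
    k_fast: float = 1.0,
) -> RunReport:
    """Run every analysis stage on a bundle directory.

    Writes ``report.json`` and ``summary.txt`` into ``out_dir`` when
    given. ``k_fast`` is the known unobstructed elongation rate held
    fixed in the stall fit. Raises on missing melting inputs; per-stage
    fit failures are flagged in the report instead.
    """
    data_dir = Path(data_dir)
    report = RunReport()
    report.provenance = {
        "package_version": __version__,
        "data_dir": data_dir.name,
        "input_hashes": {
            p.name: _sha256(p)
            for p in sorted(data_dir.glob("*.csv"))
        },
        "k_fast_per_s": k_fast,
    }
    _melting_stage(data_dir, report)
    _cd_stage(data_dir, report)
    _stall_stage(data_dir, report, k_fast)
    _cleavage_stage(data_dir, report)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        (out / "summary.txt").write_text(report.summary())
    return report
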
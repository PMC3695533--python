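"""Exponential dependence of the proteolysis ratio on quadruplex stability.

In cells, expression of the receptor (or its GFP fusions) from mRNAs
carrying the synonymous QFP variants yields a full-length band and a
cleaved band on the gel. The analysis endpoint is the cleaved/full-length
intensity ratio, normalized to the non-folding A-mutant standard:

    rho(variant) = (cleaved/full)_variant / (cleaved/full)_A-mutant

plotted against x = -dG37 (the quadruplex stability, kcal/mol; the
A-mutant sits at x = 0 with rho = 1 by construction). If stalling
depth — and through it proteolysis sensitivity — scales exponentially
with stability, the points follow a single exponential. The default
"anchored" fit rho(x) = exp(b x) passes through (0, 1) exactly; an
affine variant rho(x) = c + a exp(b x) is available for sensitivity
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CleavageTable", "RatioSummary", "ExpFit",
    "relative_ratios", "fit_exponential", "predict_ratio",
    "read_cleavage_csv", "write_cleavage_csv",
]

STANDARD_VARIANT_DG37 = 0.0   # the A-mutant standard never folds


@dataclass(frozen=True)
class CleavageTable:
    """Band intensities per variant and replicate.

    Columns: ``variant``, ``dG37_kcal_mol`` (0 for the standard),
    ``replicate``, ``intensity_full``, ``intensity_cleaved``. All
    intensities must be positive; a standard (dG37 = 0) row set must be
    present so ratios can be normalized.
    """

    data: pd.DataFrame

    REQUIRED = ("variant", "dG37_kcal_mol", "replicate",
                "intensity_full", "intensity_cleaved")

    def __post_init__(self) -> None:
        df = self.data
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
        if (df["intensity_full"] <= 0).any() or (
                df["intensity_cleaved"] <= 0).any():
            raise ValueError("band intensities must be positive")
        if not (df["dG37_kcal_mol"] == STANDARD_VARIANT_DG37).any():
            raise ValueError("no standard (dG37 = 0) rows in table")

    @property
    def standard_variant(self) -> str:
        rows = self.data[self.data["dG37_kcal_mol"] == STANDARD_VARIANT_DG37]
        return str(rows["variant"].iloc[0])


@dataclass(frozen=True)
class RatioSummary:
    """Normalized cleavage ratios with replicate statistics."""

    variant: str
    dG37: float
    rho_mean: float
    rho_sd: float | None
    n_replicates: int

    @property
    def x(self) -> float:
        """Stability coordinate -dG37 used on the fit axis."""
        return -self.dG37


@dataclass(frozen=True)
class ExpFit:
    """Fitted single-exponential rho(x).

    ``form_id`` is ``anchored`` for rho = exp(b x) (exact through
    (0, 1)) or ``affine`` for rho = c + a exp(b x).
    """

    b: float
    form_id: str = "anchored"
    a: float = 1.0
    c: float = 0.0
    residual_rms: float = 0.0

    def __call__(self, x):
        return predict_ratio(x, self)


def relative_ratios(table: CleavageTable) -> list[RatioSummary]:
    """Cleaved/full ratios normalized replicate-wise to the standard.

    Each replicate's ratio is divided by the same replicate's standard
    ratio (gels are paired by replicate), then summarized as mean +/- SD
    across replicates; SD is None for a single replicate.
    """
    df = table.data
    ratios = df.assign(ratio=df["intensity_cleaved"] / df["intensity_full"])
    std = ratios[ratios["dG37_kcal_mol"] == STANDARD_VARIANT_DG37]
    std_by_rep = std.set_index("replicate")["ratio"]
    out = []
    for (variant, dG37), grp in ratios.groupby(["variant", "dG37_kcal_mol"],
                                               sort=False):
        try:
            rho = (grp.set_index("replicate")["ratio"]
                   / std_by_rep.loc[grp["replicate"]]).to_numpy()
        except KeyError as exc:
            raise ValueError(
                f"{variant}: replicate {exc.args[0]!r} has no matching "
                "standard row"
            ) from None
        out.append(RatioSummary(
            variant=str(variant), dG37=float(dG37),
            rho_mean=float(np.mean(rho)),
            rho_sd=float(np.std(rho, ddof=1)) if rho.size > 1 else None,
            n_replicates=int(rho.size),
        ))
    return out


def fit_exponential(
    x: np.ndarray,
    rho: np.ndarray,
    sd: np.ndarray | None = None,
    form: str = "anchored",
) -> ExpFit:
    """Least-squares single-exponential fit of rho against x = -dG37.

    Fitted on the ratio scale (not log rho) because the reported
    uncertainties are on the ratios; ``sd`` enables 1/sd weighting.
    Requires >= 3 distinct x values including the x = 0 anchor. If all
    ratios are equal the slope is exactly 0 (with a warning, since the
    data then carry no stability signal).
    """
    x = np.asarray(x, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("ratios must be positive")
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct stability values")
    if not np.any(x == 0):
        raise ValueError("the x = 0 standard point must be included")
    if np.ptp(rho) == 0:
        warnings.warn("all ratios equal: returning b = 0", stacklevel=2)
        return ExpFit(b=0.0, form_id=form, residual_rms=0.0)
    sigma = np.asarray(sd, float) if sd is not None else None

    if form == "anchored":
        def model(xv, b):
            return np.exp(b * xv)
        p0 = [max(np.log(rho.max()) / max(x.max(), 1e-9), 1e-3)]
    elif form == "affine":
        def model(xv, b, a, c):
            return c + a * np.exp(b * xv)
        p0 = [max(np.log(max(rho.max(), 1.1)) / max(x.max(), 1e-9), 1e-3),
              1.0, 0.0]
    else:
        raise ValueError("form must be 'anchored' or 'affine'")

    popt, _ = curve_fit(model, x, rho, p0=p0, sigma=sigma,
                        absolute_sigma=False, maxfev=20000)
    resid = model(x, *popt) - rho
    rms = float(np.sqrt(np.mean(resid ** 2)))
    if form == "anchored":
        return ExpFit(b=float(popt[0]), form_id="anchored",
                      residual_rms=rms)
    return ExpFit(b=float(popt[0]), a=float(popt[1]), c=float(popt[2]),
                  form_id="affine", residual_rms=rms)


def predict_ratio(x, fit: ExpFit):
    """Predicted normalized ratio at stability x = -dG37 (x >= 0)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x = -dG37 must be >= 0")
    if fit.form_id == "anchored":
        out = np.exp(fit.b * x)
    else:
        out = fit.c + fit.a * np.exp(fit.b * x)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# CSV I/O


def read_cleavage_csv(path: str | Path) -> CleavageTable:
    return CleavageTable(pd.read_csv(path))


def write_cleavage_csv(table: CleavageTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, float_format="%.10g")
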
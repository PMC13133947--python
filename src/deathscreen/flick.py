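"""Plate-fluorescence viability metrics: LF, FV, RV and GR.

Lysis-based kinetic death assays read three fluorescence channels per
condition: a kinetic dead-cell signal (membrane-impermeable dye), an
endpoint total-cell signal after lysis, and a T0 total-cell signal from a
plate lysed at drugging time.  Live-cell signal is inferred by subtraction,
and four response metrics follow:

======  ==============================================================
LF      lethal fraction, dead/(live+dead)
FV      fractional viability, live/(live+dead) = 1 - LF (death-specific)
RV      relative viability, treated live / untreated live (growth-biased)
GR      normalized growth-rate inhibition,
        2**(log2(LT/L0) / log2(LU/L0)) - 1
======  ==============================================================

Fluorescence is assumed proportional to cell number with a single gain per
plate; all metrics are ratios, so the gain cancels.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "ViabilityPoint",
    "ResponseMetrics",
    "infer_live",
    "lethal_fraction",
    "fractional_viability",
    "relative_viability",
    "gr_value",
    "drug_induced_lf",
    "fit_dose_response",
    "DoseResponseFit",
    "plate_to_metrics",
]


@dataclass(frozen=True)
class ViabilityPoint:
    """Live/dead/total cell-equivalent fluorescence at one timepoint."""

    live: float
    dead: float
    total: float
    t: float
    condition: str = ""

    def __post_init__(self):
        if self.live < 0 or self.dead < 0 or self.total < 0:
            raise ValueError("fluorescence components must be non-negative")


@dataclass(frozen=True)
class ResponseMetrics:
    """The four response metrics at one (dose, timepoint)."""

    LF: float
    FV: float
    RV: float
    GR: float
    dose: float
    t: float


def infer_live(total_endpoint: float, dead_endpoint: float) -> float:
    """Live signal = total - dead; clamps small negative noise to 0."""
    live = total_endpoint - dead_endpoint
    if live < 0:
        warnings.warn(
            f"dead signal ({dead_endpoint:g}) exceeds total ({total_endpoint:g}); "
            "clamping live to 0",
            stacklevel=2,
        )
        live = 0.0
    return live


def fractional_viability(live: float, dead: float) -> float:
    """FV = live/(live+dead); NaN when both are zero."""
    tot = live + dead
    if tot <= 0:
        return float("nan")
    return live / tot


def lethal_fraction(live: float, dead: float) -> float:
    """LF = dead/(live+dead) = 1 - FV; NaN when both are zero."""
    fv = fractional_viability(live, dead)
    return 1.0 - fv if not math.isnan(fv) else fv


def relative_viability(live_treated_t: float, live_untreated_t: float) -> float:
    """RV = treated live / untreated live; NaN + warning when untreated is 0."""
    if live_untreated_t <= 0:
        warnings.warn("untreated live population is zero; RV undefined", stacklevel=2)
        return float("nan")
    return live_treated_t / live_untreated_t


def gr_value(live_treated_t: float, live_t0: float, live_untreated_t: float) -> float:
    """Normalized growth-rate inhibition.

    GR = 2**( log2(LT/L0) / log2(LU/L0) ) - 1.  GR 1 means the treated
    population grew like the untreated one, 0 means stasis at the T0 level,
    negative values mean population shrinkage.  Undefined (NaN + warning)
    when the untreated population did not grow.
    """
    if live_t0 <= 0:
        raise ValueError("T0 live population must be positive")
    if live_untreated_t <= live_t0:
        warnings.warn(
            "untreated population did not grow; GR normalization undefined",
            stacklevel=2,
        )
        return float("nan")
    if live_treated_t <= 0:
        return -1.0  # limit of a fully eliminated population
    ratio = math.log2(live_treated_t / live_t0) / math.log2(live_untreated_t / live_t0)
    return 2.0**ratio - 1.0


def drug_induced_lf(
    lf_treated: np.ndarray | pd.Series,
    lf_vehicle: np.ndarray | pd.Series | None,
) -> np.ndarray:
    """Vehicle-corrected lethal fraction, ``max(LF_drug - LF_vehicle, 0)``.

    Background death is not drug-induced; subtracting the matched vehicle
    series and flooring at 0 isolates the drug's contribution.  If no
    vehicle series is available the raw LF is returned and a warning marks
    it uncorrected.
    """
    lf_treated = np.asarray(lf_treated, dtype=float)
    if lf_vehicle is None:
        warnings.warn("no vehicle series; returning uncorrected LF", stacklevel=2)
        return lf_treated.copy()
    lf_vehicle = np.asarray(lf_vehicle, dtype=float)
    if lf_vehicle.shape != lf_treated.shape:
        raise ValueError("treated and vehicle LF series must align by timepoint")
    return np.maximum(lf_treated - lf_vehicle, 0.0)


@dataclass
class DoseResponseFit:
    """4-parameter logistic fit of a response metric against dose.

    ``f(D) = lower + (upper - lower) / (1 + (D/ec50)**hill)``

    A positive ``hill`` gives a decreasing curve (the usual viability
    convention); fits to increasing data converge to negative ``hill``.
    """

    upper: float
    lower: float
    ec50: float
    hill: float
    residual_norm: float
    flag: str = ""

    def predict(self, doses) -> np.ndarray:
        d = np.asarray(doses, dtype=float)
        return _four_pl(d, self.upper, self.lower, self.ec50, self.hill)


def _four_pl(d, upper, lower, ec50, hill):
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, d / ec50, 0.0)
        out = lower + (upper - lower) / (1.0 + ratio**hill)
    return np.where(d > 0, out, upper)


def fit_dose_response(doses, values) -> DoseResponseFit:
    """Least-squares 4PL fit; needs >= 4 dose levels.

    Non-convergence falls back to a flat line at the mean response with a
    ``flat_fallback`` flag; near-constant data fit with hill ~ 0 and are
    flagged ``degenerate``.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(d) & np.isfinite(y)
    d, y = d[ok], y[ok]
    if len(np.unique(d)) < 4:
        raise ValueError("need at least 4 dose levels for a 4PL fit")
    if np.ptp(y) < 1e-12:
        return DoseResponseFit(
            upper=float(y.mean()), lower=float(y.mean()), ec50=float(np.median(d[d > 0]) or 1.0),
            hill=0.0, residual_norm=0.0, flag="degenerate",
        )
    pos = d[d > 0]
    p0 = (float(y.max()), float(y.min()), float(np.median(pos)), 1.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_four_pl, d, y, p0=p0, maxfev=20000)
        resid = float(np.linalg.norm(y - _four_pl(d, *popt)))
        return DoseResponseFit(*(float(p) for p in popt), residual_norm=resid)
    except RuntimeError:
        mean = float(y.mean())
        resid = float(np.linalg.norm(y - mean))
        return DoseResponseFit(mean, mean, float(np.median(pos)), 0.0, resid,
                               flag="flat_fallback")


def plate_to_metrics(
    plate: pd.DataFrame,
    t: float,
    time_tol: float = 1.0,
) -> pd.DataFrame:
    """Collapse a tidy plate table into per-(drug, dose) response metrics.

    Expects the plate schema of :mod:`deathscreen.io` (columns ``drug``,
    ``dose``, ``timepoint``, ``kind`` in {T0_lysed, dead_kinetic,
    endpoint_lysed}, ``fluorescence``); replicate wells are averaged.
    Timepoints are matched to ``t`` by nearest neighbour within
    ``time_tol`` hours.  The dose-0 rows of each drug serve as the
    untreated reference for RV and GR; the vehicle LF series corrects LF
    into drug-induced LF downstream.
    """
    required = {"drug", "dose", "timepoint", "kind", "fluorescence"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")

    def _signal(sub: pd.DataFrame, kind: str, at: float | None) -> float:
        rows = sub[sub["kind"] == kind]
        if at is not None:
            dt = (rows["timepoint"] - at).abs()
            rows = rows[dt <= time_tol]
        if rows.empty:
            return float("nan")
        return float(rows["fluorescence"].mean())

    t0_live = _signal(plate, "T0_lysed", None) - _signal(plate, "dead_kinetic", 0.0)
    if not np.isfinite(t0_live):
        t0_live = _signal(plate, "T0_lysed", None)

    out = []
    for drug, sub in plate.groupby("drug"):
        if not (sub["kind"] == "endpoint_lysed").any():
            continue  # e.g. the shared T0-lysed wells carry no drug label
        untr = sub[sub["dose"] == 0.0]
        u_total = _signal(untr, "endpoint_lysed", t)
        u_dead = _signal(untr, "dead_kinetic", t)
        u_live = infer_live(u_total, u_dead)
        for dose, cell in sub.groupby("dose"):
            total = _signal(cell, "endpoint_lysed", t)
            dead = _signal(cell, "dead_kinetic", t)
            live = infer_live(total, dead)
            lf = lethal_fraction(live, dead)
            out.append(
                {
                    "drug": drug,
                    "dose": dose,
                    "t": t,
                    "LF": lf,
                    "FV": fractional_viability(live, dead),
                    "RV": relative_viability(live, u_live),
                    "GR": gr_value(live, t0_live, u_live),
                }
            )
    df = pd.DataFrame(out).sort_values(["drug", "dose"]).reset_index(drop=True)
    # vehicle-correct LF within each drug series
    corrected = []
    for _, sub in df.groupby("drug", sort=False):
        base = float(sub.loc[sub["dose"] == 0.0, "LF"].iloc[0]) if (sub["dose"] == 0.0).any() else None
        lf = drug_induced_lf(sub["LF"].to_numpy(), np.full(len(sub), base) if base is not None else None)
        corrected.append(pd.Series(lf, index=sub.index))
    df["LF_drug_induced"] = pd.concat(corrected).sort_index()
    return df
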
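"""Two-drug dose-matrix synergy analysis on death-specific and conventional readouts.

The same dose matrix is scored twice: with the death-specific fractional
viability (FV) and with the conventional relative viability (RV).  The
"effect" entering every synergy computation is the affected fraction,
``fa = 1 - FV`` (lethality) or ``fa = 1 - RV``.  Because RV is blind to
death and FV is blind to growth inhibition, the two analyses can disagree
on the same plate — a drug pair may synergise for killing while remaining
nearly additive for population suppression.

Three classical references are implemented:

* the median-effect model ``log(fa/fu) = m (log D - log Dm)`` fitted per
  single agent, giving equipotent doses ``Dx = Dm (x/(1-x))**(1/m)``;
* Loewe additivity: combination index ``CI = d1/Dx1 + d2/Dx2`` (CI < 1
  synergy), isobolograms, and fixed-ratio expected curves;
* Bliss independence ``E = E1 + E2 - E1*E2`` with per-cell deviation DBI.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "DoseMatrix",
    "MedianEffectFit",
    "fit_median_effect",
    "combination_index",
    "fixed_ratio_ci",
    "isobol",
    "bliss_deviation",
    "fixed_ratio_curve",
    "SynergyAnalysis",
]


@dataclass
class DoseMatrix:
    """Two-drug response grid.

    ``fv`` and ``rv`` have shape (len(doses1), len(doses2)); row i, column
    j holds the response at (doses1[i], doses2[j]).  Both dose axes must
    include 0 so single-agent margins and the untreated anchor exist.
    """

    doses1: np.ndarray
    doses2: np.ndarray
    fv: np.ndarray
    rv: np.ndarray
    drug1: str = "drug1"
    drug2: str = "drug2"
    replicates: int = 1

    def __post_init__(self):
        self.doses1 = np.asarray(self.doses1, dtype=float)
        self.doses2 = np.asarray(self.doses2, dtype=float)
        self.fv = np.asarray(self.fv, dtype=float)
        self.rv = np.asarray(self.rv, dtype=float)
        if self.doses1[0] != 0.0 or self.doses2[0] != 0.0:
            raise ValueError("dose axes must start at 0 (untreated anchor)")
        shape = (len(self.doses1), len(self.doses2))
        if self.fv.shape != shape or self.rv.shape != shape:
            raise ValueError(f"response matrices must have shape {shape}")
        if not (np.isfinite(self.fv).all() and np.isfinite(self.rv).all()):
            raise ValueError("responses must be finite")
        if ((self.fv < 0) | (self.fv > 1)).any():
            raise ValueError("FV must lie in [0, 1]")

    def effect(self, readout: str) -> np.ndarray:
        """Affected fraction under the named readout, clipped to [0, 1]."""
        if readout == "FV":
            return 1.0 - self.fv
        if readout == "RV":
            return np.clip(1.0 - self.rv, 0.0, 1.0)
        raise ValueError(f"unknown readout {readout!r}")

    @classmethod
    def from_long(cls, df: pd.DataFrame, **kwargs) -> "DoseMatrix":
        """Build from a long table with columns dose1, dose2, FV, RV."""
        required = {"dose1", "dose2", "FV", "RV"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long dose matrix missing columns: {sorted(missing)}")
        agg = df.groupby(["dose1", "dose2"])[["FV", "RV"]].mean()
        fv = agg["FV"].unstack()
        rv = agg["RV"].unstack()
        reps = int(df.groupby(["dose1", "dose2"]).size().max())
        return cls(fv.index.to_numpy(), fv.columns.to_numpy(),
                   fv.to_numpy(), rv.to_numpy(), replicates=reps, **kwargs)

    def to_long(self) -> pd.DataFrame:
        i, j = np.meshgrid(range(len(self.doses1)), range(len(self.doses2)),
                           indexing="ij")
        return pd.DataFrame({
            "dose1": self.doses1[i.ravel()],
            "dose2": self.doses2[j.ravel()],
            "FV": self.fv.ravel(),
            "RV": self.rv.ravel(),
        })


@dataclass
class MedianEffectFit:
    """Median-effect (Hill-type) fit of a single-agent dose curve.

    ``m`` is the slope (sigmoidicity), ``Dm`` the dose of median effect
    (fa = 0.5).  Only doses with effect strictly inside (0, 1) enter the
    fit; clipped points are dropped and logged.
    """

    m: float
    Dm: float
    residual: float
    n_points: int
    effect_definition: str = ""

    def dx(self, x: float) -> float:
        """Dose producing affected fraction x."""
        if not (0.0 < x < 1.0):
            raise ValueError("effect level must lie in (0, 1)")
        return self.Dm * (x / (1.0 - x)) ** (1.0 / self.m)

    def fa(self, dose) -> np.ndarray:
        """Affected fraction at dose(s) under the fitted model."""
        d = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            out = 1.0 / (1.0 + (self.Dm / np.where(d > 0, d, np.nan)) ** self.m)
        return np.where(d > 0, out, 0.0)


def fit_median_effect(
    doses, effects, effect_definition: str = ""
) -> MedianEffectFit:
    """Least-squares fit of the linearised median-effect equation.

    Regresses ``log(fa/(1-fa))`` on ``log D`` over doses with fa strictly
    in (0, 1); needs >= 3 usable points.  Non-monotone data still fit; the
    residual flags quality.
    """
    d = np.asarray(doses, dtype=float)
    fa = np.asarray(effects, dtype=float)
    usable = (d > 0) & (fa > 0.0) & (fa < 1.0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("median-effect fit dropped %d clipped/zero-dose points", n_dropped)
    d, fa = d[usable], fa[usable]
    if len(d) < 3:
        raise ValueError(
            f"median-effect fit needs >= 3 doses with effect in (0,1); have {len(d)}"
        )
    x = np.log10(d)
    y = np.log10(fa / (1.0 - fa))
    m, intercept = np.polyfit(x, y, 1)
    log_dm = -intercept / m
    resid = float(np.linalg.norm(y - (m * x + intercept)))
    return MedianEffectFit(m=float(m), Dm=float(10 ** log_dm), residual=resid,
                           n_points=len(d), effect_definition=effect_definition)


def combination_index(
    d1: float,
    d2: float,
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    level: float = 0.5,
) -> float:
    """Chou-Talalay CI of the combo (d1, d2) at an effect level.

    ``CI = d1/Dx1 + d2/Dx2`` where Dxi is the single-agent dose producing
    the level alone.  CI < 1 synergy, 1 additivity, > 1 antagonism; for
    fixed-ratio dosing 1/CI is the fold reduction in total dose relative
    to additivity.
    """
    return d1 / fit1.dx(level) + d2 / fit2.dx(level)


def fixed_ratio_ci(
    matrix: DoseMatrix,
    readout: str = "FV",
    level: float = 0.5,
    diagonal: bool = True,
) -> tuple[float, float]:
    """CI at a level for the combination dosed along the grid diagonal.

    Fits the median-effect model to both single agents and to the combo
    series (diagonal cells, indexed by drug-1 dose), finds the combo dose
    pair reaching the level, and returns (CI, fold_reduction = 1/CI).
    """
    eff = matrix.effect(readout)
    fit1 = fit_median_effect(matrix.doses1, eff[:, 0], readout)
    fit2 = fit_median_effect(matrix.doses2, eff[0, :], readout)
    n = min(len(matrix.doses1), len(matrix.doses2))
    combo_d1 = matrix.doses1[1:n]
    combo_d2 = matrix.doses2[1:n]
    combo_eff = np.array([eff[i, i] for i in range(1, n)])
    fit_combo = fit_median_effect(combo_d1, combo_eff, readout)
    d1_at_level = fit_combo.dx(level)
    # dose-2 component scales with its own axis along the diagonal
    ratio = np.median(combo_d2 / combo_d1)
    d2_at_level = ratio * d1_at_level
    ci = combination_index(d1_at_level, d2_at_level, fit1, fit2, level)
    return float(ci), float(1.0 / ci)


def _interp_axis(idx: np.ndarray, doses: np.ndarray) -> np.ndarray:
    """Map fractional grid indices to dose values by linear interpolation."""
    return np.interp(idx, np.arange(len(doses)), doses)


def isobol(
    matrix: DoseMatrix,
    level: float = 0.5,
    readout: str = "FV",
) -> dict:
    """Iso-effect contour and its Loewe additivity reference line.

    Returns ``{"contours": [(d1, d2) polylines], "reference":
    ((Dx1, 0), (0, Dx2)), "flag": str}``.  The reference joins the
    single-agent doses reaching the level; a contour bowed inside that
    line indicates synergy.  An unreached level returns empty contours
    with a flag.
    """
    eff = matrix.effect(readout)
    flag = ""
    if eff.max() < level or eff.min() > level:
        return {"contours": [], "reference": None, "flag": "level_not_crossed"}
    raw = measure.find_contours(eff, level)
    contours = []
    for poly in raw:
        d1 = _interp_axis(poly[:, 0], matrix.doses1)
        d2 = _interp_axis(poly[:, 1], matrix.doses2)
        contours.append(np.column_stack([d1, d2]))
    try:
        fit1 = fit_median_effect(matrix.doses1, eff[:, 0], readout)
        fit2 = fit_median_effect(matrix.doses2, eff[0, :], readout)
        reference = ((fit1.dx(level), 0.0), (0.0, fit2.dx(level)))
    except ValueError:
        reference, flag = None, "single_agent_fit_failed"
    return {"contours": contours, "reference": reference, "flag": flag}


def bliss_deviation(matrix: DoseMatrix, readout: str = "FV") -> dict:
    """Deviation from Bliss independence per combination cell.

    ``E_bliss = E1 + E2 - E1*E2`` from the single-agent margins;
    ``DBI = E_obs - E_bliss`` (positive = stronger than independent).
    Returns the DBI surface plus mean and max over combination cells.
    """
    eff = matrix.effect(readout)
    e1 = eff[:, 0]
    e2 = eff[0, :]
    if np.isnan(e1).any() or np.isnan(e2).any():
        raise ValueError("single-agent margins are incomplete")
    e_bliss = e1[:, None] + e2[None, :] - e1[:, None] * e2[None, :]
    dbi = eff - e_bliss
    combo = dbi[1:, 1:]
    return {
        "dbi": dbi,
        "bliss_expected": e_bliss,
        "mean": float(combo.mean()),
        "max": float(combo.max()),
    }


def fixed_ratio_curve(
    matrix: DoseMatrix, readout: str = "FV"
) -> pd.DataFrame:
    """Observed vs Loewe-expected effect along the grid diagonal ray.

    The expected effect at a dose pair (d1, d2) is the level x solving
    ``d1/Dx1(x) + d2/Dx2(x) = 1`` under the single-agent median-effect
    fits.  Returns a frame with columns dose1, dose2, observed, expected.
    """
    eff = matrix.effect(readout)
    fit1 = fit_median_effect(matrix.doses1, eff[:, 0], readout)
    fit2 = fit_median_effect(matrix.doses2, eff[0, :], readout)
    n = min(len(matrix.doses1), len(matrix.doses2))
    rows = []
    for i in range(1, n):
        d1, d2 = matrix.doses1[i], matrix.doses2[i]

        def loewe_gap(x, d1=d1, d2=d2):
            return d1 / fit1.dx(x) + d2 / fit2.dx(x) - 1.0

        try:
            expected = brentq(loewe_gap, 1e-9, 1.0 - 1e-9)
        except ValueError:
            expected = float("nan")
        rows.append({"dose1": d1, "dose2": d2,
                     "observed": float(eff[i, i]), "expected": expected})
    return pd.DataFrame(rows)


class SynergyAnalysis:
    """All synergy metrics of one dose matrix, on both readouts.

    A thin results object: construction runs every computation; attributes
    hold CI, DBI and isobol outputs per readout; ``summary()`` prints the
    comparison table.  Metadata records the effect definitions and the
    DBI convention (observed minus expected, summarised by mean and max).
    """

    def __init__(self, matrix: DoseMatrix, level: float = 0.5):
        self.matrix = matrix
        self.level = level
        self.results: dict[str, dict] = {}
        for readout in ("FV", "RV"):
            entry: dict = {}
            try:
                ci, fold = fixed_ratio_ci(matrix, readout, level)
                entry["CI"], entry["fold_reduction"] = ci, fold
            except ValueError as exc:
                entry["CI"] = entry["fold_reduction"] = float("nan")
                entry["flag"] = str(exc)
            bl = bliss_deviation(matrix, readout)
            entry["DBI_mean"], entry["DBI_max"] = bl["mean"], bl["max"]
            entry["isobol"] = isobol(matrix, level, readout)
            self.results[readout] = entry
        self.metadata = {
            "effect_FV": "1 - FV (lethality)",
            "effect_RV": "1 - RV",
            "DBI_convention": "observed minus Bliss-expected effect; mean and max over combination cells",
            "CI_level": level,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for readout, entry in self.results.items():
            rows.append({
                "readout": readout,
                "CI": entry["CI"],
                "fold_reduction": entry["fold_reduction"],
                "DBI_mean": entry["DBI_mean"],
                "DBI_max": entry["DBI_max"],
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"Two-drug synergy analysis ({self.matrix.drug1} x {self.matrix.drug2})",
            f"  CI evaluated at {self.level:.0%} effect; CI < 1 = synergy",
            "",
            df.to_string(index=False, float_format=lambda x: f"{x:.4g}"),
        ]
        return "\n".join(lines)

    def plot_isobologram(self, readout: str = "FV", ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        iso = self.results[readout]["isobol"]
        for poly in iso["contours"]:
            ax.plot(poly[:, 0], poly[:, 1], "-", color="C0")
        if iso["reference"] is not None:
            (x1, y1), (x2, y2) = iso["reference"]
            ax.plot([x1, x2], [y1, y2], "--", color="gray", label="additivity")
        ax.set_xlabel(f"{self.matrix.drug1} dose")
        ax.set_ylabel(f"{self.matrix.drug2} dose")
        ax.legend()
        return ax
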
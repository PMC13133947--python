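"""Live/dead birth-death population model and GRADE rate inversion.

The model tracks a live population L that grows exponentially at net rate
``k = g*ln2 - d`` (g in doublings/hour, d in per-capita deaths/hour) and a
dead population D fed by the live one at rate ``d*L``.  Dead cells persist
(no clearance), matching cumulative dead-cell fluorescence readouts over
assay windows of ~72 h.

GRADE (Growth Rate Adjusted for DEath) juxtaposes the normalized growth-rate
inhibition value GR with the lethal fraction LF and inverts the pair into a
(proliferation, death) rate pair: GR pins down the net rate k of the treated
population relative to untreated, and LF then determines the death rate d by
monotone root finding, leaving g = (k + d)/ln2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

LN2 = math.log(2.0)

__all__ = [
    "RatePair",
    "PopulationState",
    "simulate_live_dead",
    "grade_coordinates",
    "infer_rates",
    "GradeModel",
    "GradeResults",
]


@dataclass(frozen=True)
class RatePair:
    """Proliferation and death rates of a cell population.

    Parameters
    ----------
    g : float
        Proliferation rate in population doublings per hour (>= 0).
    d : float
        Per-capita death rate, fraction of live cells per hour (>= 0).
    """

    g: float
    d: float

    def __post_init__(self) -> None:
        if not (self.g >= 0.0):
            raise ValueError(f"proliferation rate g must be >= 0, got {self.g}")
        if not (self.d >= 0.0):
            raise ValueError(f"death rate d must be >= 0, got {self.d}")
        if not math.isfinite(self.k):
            raise ValueError("net rate k must be finite")

    @property
    def k(self) -> float:
        """Net exponential rate per hour, ``g*ln2 - d``."""
        return self.g * LN2 - self.d


@dataclass(frozen=True)
class PopulationState:
    """Live/dead population sizes at a timepoint (hours)."""

    L: float
    D: float
    t: float


def simulate_live_dead(
    L0: float, D0: float, rates: RatePair, t: float
) -> PopulationState:
    """Closed-form solution of dL/dt = k*L, dD/dt = d*L.

    ``L(t) = L0*exp(k*t)``; ``D(t) = D0 + d*L0*(exp(k*t)-1)/k`` for k != 0,
    with the continuous limit ``D0 + d*L0*t`` at k = 0.
    """
    if L0 < 0 or D0 < 0:
        raise ValueError("initial populations must be non-negative")
    if t < 0:
        raise ValueError("time must be non-negative")
    k = rates.k
    kt = k * t
    L = L0 * math.exp(kt)
    # expm1(kt)/k is numerically stable through k -> 0
    integral = L0 * t if kt == 0.0 else L0 * math.expm1(kt) / k
    D = D0 + rates.d * integral
    return PopulationState(L=L, D=D, t=t)


def lethal_fraction_at(rates: RatePair, t: float, L0: float = 1.0, D0: float = 0.0) -> float:
    """LF(t) = D(t)/(L(t)+D(t)) under the birth-death model."""
    s = simulate_live_dead(L0, D0, rates, t)
    tot = s.L + s.D
    return s.D / tot if tot > 0 else float("nan")


def grade_coordinates(metrics) -> list[tuple[float, float]]:
    """Pair GR with drug-induced LF per dose for GRADE plotting/inference.

    Accepts an iterable of objects/records with ``GR`` and ``LF`` attributes
    or keys (e.g. :class:`deathscreen.flick.ResponseMetrics` rows, or a
    pandas DataFrame) and returns [(GR, LF), ...] in input order.
    """
    pairs = []
    try:  # DataFrame path
        rows = metrics.itertuples()
    except AttributeError:
        rows = metrics
    for m in rows:
        gr = m.GR if hasattr(m, "GR") else m["GR"]
        lf = m.LF if hasattr(m, "LF") else m["LF"]
        pairs.append((float(gr), float(lf)))
    return pairs


def infer_rates(
    GR: float,
    LF: float,
    t: float,
    untreated_rates: RatePair,
    D0_frac: float = 0.0,
    bracket: tuple[float, float] = (0.0, 1.0),
    xtol: float = 1e-10,
) -> RatePair:
    """Invert an observed (GR, LF) pair at time t into a RatePair.

    The treated net rate follows from GR: ``k = k0*log2(GR+1)`` where k0 is
    the untreated net rate.  The death rate d is then the unique root of
    ``LF_model(d; k, t) = LF`` — LF is strictly increasing in d at fixed k —
    found by bracketed root finding on ``bracket`` (per hour).  The
    proliferation rate is ``g = (k+d)/ln2``, floored at 0.

    Parameters
    ----------
    D0_frac : float
        Dead cells present at T0 as a fraction of the live T0 population
        (basal death seed); default 0.
    """
    if not GR > -1:
        raise ValueError("GR must exceed -1")
    if not (0.0 <= LF < 1.0):
        raise ValueError("LF must lie in [0, 1)")
    if t <= 0:
        raise ValueError("t must be positive")
    k0 = untreated_rates.k
    if k0 <= 0:
        raise ValueError("untreated population must have positive net rate k0")
    k = k0 * math.log2(GR + 1.0)

    def lf_of_d(d: float) -> float:
        # LF under net rate k and death rate d (g implied by g = (k+d)/ln2)
        kt = k * t
        L = math.exp(kt)
        integral = t if kt == 0.0 else math.expm1(kt) / k
        D = D0_frac + d * integral
        return D / (L + D)

    lf_floor = lf_of_d(0.0)
    if LF <= lf_floor + 1e-15:
        d = 0.0
    else:
        lo, hi = bracket
        if lf_of_d(hi) < LF:
            raise ValueError(
                f"no root in bracket [{lo}, {hi}]: LF={LF} exceeds "
                f"LF({hi}/h)={lf_of_d(hi):.6f} at net rate k={k:.6g}/h"
            )
        d = brentq(lambda x: lf_of_d(x) - LF, lo, hi, xtol=xtol)
    g = (k + d) / LN2
    if g < 0:
        g = 0.0
    return RatePair(g=g, d=d)


class GradeModel:
    """GRADE decomposition of a drug response into growth and death rates.

    Built from per-dose (GR, LF) observations at a common assay endpoint,
    together with the untreated reference rates measured on the same cells.

    Parameters
    ----------
    gr, lf : array-like
        GR values and drug-induced lethal fractions, one entry per dose.
    t : float
        Assay duration, hours.
    untreated_rates : RatePair
        Proliferation/death rates of the untreated population.
    doses : array-like, optional
        Dose labels carried through to the results table.
    D0_frac : float
        Basal dead fraction at T0 (see :func:`infer_rates`).
    """

    def __init__(self, gr, lf, t, untreated_rates, doses=None, D0_frac=0.0):
        self.gr = np.asarray(gr, dtype=float)
        self.lf = np.asarray(lf, dtype=float)
        if self.gr.shape != self.lf.shape:
            raise ValueError("gr and lf must have matching shapes")
        self.t = float(t)
        self.untreated_rates = untreated_rates
        self.doses = None if doses is None else np.asarray(doses, dtype=float)
        if self.doses is not None and self.doses.shape != self.gr.shape:
            raise ValueError("doses must match gr/lf shape")
        self.D0_frac = float(D0_frac)

    @classmethod
    def from_dataframe(cls, df, t, untreated_rates, **kwargs):
        """Build from a tidy frame with columns GR, LF and optionally dose."""
        doses = df["dose"].to_numpy() if "dose" in df.columns else None
        return cls(df["GR"].to_numpy(), df["LF"].to_numpy(), t,
                   untreated_rates, doses=doses, **kwargs)

    def fit(self) -> "GradeResults":
        """Invert every (GR, LF) pair; returns a :class:`GradeResults`."""
        rates, flags = [], []
        for gr, lf in zip(self.gr, self.lf):
            flag = ""
            if not (np.isfinite(gr) and np.isfinite(lf)):
                rates.append(None)
                flags.append("undefined_input")
                continue
            rp = infer_rates(gr, lf, self.t, self.untreated_rates,
                             D0_frac=self.D0_frac)
            if rp.d == 0.0 and lf > 0:
                flag = "lf_at_or_below_basal"
            if rp.g == 0.0 and rp.k < -rp.d:
                flag = (flag + ";" if flag else "") + "g_floored"
            rates.append(rp)
            flags.append(flag)
        return GradeResults(self, rates, flags)


class GradeResults:
    """Per-dose inferred rate pairs from a :class:`GradeModel` fit."""

    def __init__(self, model: GradeModel, rates: list[RatePair], flags: list[str]):
        self.model = model
        self.rates = rates
        self.flags = flags

    @property
    def g(self) -> np.ndarray:
        return np.array([r.g if r is not None else np.nan for r in self.rates])

    @property
    def d(self) -> np.ndarray:
        return np.array([r.d if r is not None else np.nan for r in self.rates])

    @property
    def k(self) -> np.ndarray:
        return np.array([r.k if r is not None else np.nan for r in self.rates])

    def to_frame(self):
        import pandas as pd

        data = {
            "GR": self.model.gr,
            "LF": self.model.lf,
            "g_doublings_per_h": self.g,
            "d_per_h": self.d,
            "k_per_h": self.k,
            "flags": self.flags,
        }
        if self.model.doses is not None:
            data = {"dose": self.model.doses, **data}
        return pd.DataFrame(data)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "GRADE rate inversion",
            f"  assay duration: {self.model.t:g} h",
            f"  untreated rates: g0={self.model.untreated_rates.g:.4g} "
            f"doublings/h, d0={self.model.untreated_rates.d:.4g} /h",
            "",
            df.to_string(index=False, float_format=lambda x: f"{x:.5g}"),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """GRADE plot: GR on y, drug-induced LF on x, one point per dose."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.lf, self.model.gr, "o-")
        ax.set_xlabel("drug-induced lethal fraction")
        ax.set_ylabel("GR value")
        ax.set_xlim(-0.02, 1.0)
        ax.axhline(0.0, color="grey", lw=0.5)
        return ax
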
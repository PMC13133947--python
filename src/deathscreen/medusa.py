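"""MEDUSA: mapping screen fold changes onto per-knockout growth/death rates.

A chemo-genetic profile compares four exponentially evolving populations —
knockout and wild-type cells, each with and without drug.  The conventional
treated-vs-untreated log2 fold change (L2FC) of a clone therefore conflates
its drug-induced death rate with its drug-free growth rate: a slow-growing
clone shows a positive L2FC without any change in drug response.  MEDUSA
removes this confound by modelling all four populations with the live/dead
birth-death model and inverting each clone's observed fold changes into a
single (growth, death) rate pair.

Under the infinitesimal-clone approximation (each knockout is a negligible
fraction of the library) the live-cell sequencing model gives closed forms
for the two observable contrasts of a clone with untreated growth
multiplier phi and treated rates (g_i, d_i):

    A = (k_u^KO - k_u^WT) * t_u / ln2          (untreated vs T0, relative)
    B = [(k_T^KO - k_T^WT) * t_T
         - (k_u^KO - k_u^WT) * t_u] / ln2      (treated vs untreated)

with k_u^KO = phi*g0*ln2 - d0 and k_T^KO = g_i*ln2 - d_i.  A pins down phi;
B alone cannot separate g_i from d_i, so a growth constraint closes the
system.  The default constraint is proportional inhibition — the drug
inhibits every clone's growth by the wild-type factor, g_i = phi*gT —
leaving d_i as the single unknown with a closed-form solution.  The
constraint is pluggable and is recorded in all output metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rates import LN2, RatePair
from . import stats as _stats
from .io import CountMatrix, GuideLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenTimeline",
    "KnockoutInference",
    "predict_l2fc",
    "infer_knockout_rates",
    "MedusaGrid",
    "infer_by_grid",
    "MedusaScreen",
    "MedusaResults",
    "proportional_inhibition",
]


@dataclass(frozen=True)
class ScreenTimeline:
    """Assay timing and wild-type rates anchoring the screen model.

    Wild-type rates in both arms come from plate-based GRADE measurements
    on the parental line.  Durations are the drug-exposure windows in
    hours; both arms default to 72 h.
    """

    untreated_rates: RatePair
    treated_rates: RatePair
    t_treat: float = 72.0
    t_untreat: float = 72.0

    def __post_init__(self):
        if self.t_treat <= 0 or self.t_untreat <= 0:
            raise ValueError("assay durations must be positive")


def proportional_inhibition(phi: float, timeline: ScreenTimeline) -> float:
    """Default growth constraint: g_i = phi * gT."""
    return phi * timeline.treated_rates.g


@dataclass
class KnockoutInference:
    """One clone's inferred rates and fit diagnostics."""

    phi: float
    g_i: float
    d_i: float
    residual: float = 0.0
    flag: str = ""

    @property
    def death_rescue(self) -> bool:
        return self.d_i < np.inf and self.d_i == 0.0 and "floored" in self.flag


def _ku(phi: float, timeline: ScreenTimeline) -> float:
    r = timeline.untreated_rates
    return phi * r.g * LN2 - r.d


def predict_l2fc(
    phi: float, g_i: float, d_i: float, timeline: ScreenTimeline
) -> tuple[float, float]:
    """Forward model: clone parameters -> (A, B) fold changes.

    A is the untreated-vs-T0 L2FC relative to wild type ("essentiality"
    signal); B is the treated-vs-untreated L2FC.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if g_i < 0 or d_i < 0:
        raise ValueError("treated rates must be non-negative")
    ku_wt = timeline.untreated_rates.k
    kt_wt = timeline.treated_rates.k
    ku_ko = _ku(phi, timeline)
    kt_ko = g_i * LN2 - d_i
    A = (ku_ko - ku_wt) * timeline.t_untreat / LN2
    B = ((kt_ko - kt_wt) * timeline.t_treat - (ku_ko - ku_wt) * timeline.t_untreat) / LN2
    return A, B


def infer_knockout_rates(
    A: float,
    B: float,
    timeline: ScreenTimeline,
    growth_constraint=proportional_inhibition,
    residual_tolerance: float = 1.0,
) -> KnockoutInference:
    """Closed-form inversion of (A, B) into (phi, g_i, d_i).

    phi comes from A (the knockout keeps the wild-type untreated death
    rate d0); the growth constraint fixes g_i from phi; d_i then solves B
    exactly.  A negative d_i solution is floored at 0 and the unexplained
    part of B is reported as the residual; |residual| above
    ``residual_tolerance`` (in L2FC units) flags a low-confidence fit.
    """
    if not (np.isfinite(A) and np.isfinite(B)):
        raise ValueError("A and B must be finite")
    r0 = timeline.untreated_rates
    rT = timeline.treated_rates
    ku_wt, kt_wt = r0.k, rT.k
    ku_ko = ku_wt + A * LN2 / timeline.t_untreat
    phi = (ku_ko + r0.d) / (r0.g * LN2)
    flag = ""
    if phi <= 0:
        phi = 1e-6
        flag = "phi_floored"
    g_i = growth_constraint(phi, timeline)
    kt_ko = kt_wt + (B * LN2 + (ku_ko - ku_wt) * timeline.t_untreat) / timeline.t_treat
    d_i = g_i * LN2 - kt_ko
    residual = 0.0
    if d_i < 0:
        # clone out-grows what the constraint allows; absorb into residual
        kt_floor = g_i * LN2
        b_floor = ((kt_floor - kt_wt) * timeline.t_treat
                   - (ku_ko - ku_wt) * timeline.t_untreat) / LN2
        residual = B - b_floor
        d_i = 0.0
        flag = (flag + ";" if flag else "") + "d_floored"
    if abs(residual) > residual_tolerance:
        flag = (flag + ";" if flag else "") + "low_confidence"
    return KnockoutInference(phi=phi, g_i=g_i, d_i=d_i, residual=residual, flag=flag)


class MedusaGrid:
    """Precomputed (A, B) surfaces over a (phi, d) grid for lookup inversion.

    The grid route mirrors the original simulation-based procedure: forward
    simulate the fold changes of clones across a lattice of growth
    multipliers and death rates, then invert an observation by locating it
    on the simulated surfaces with linear interpolation.  It serves as an
    independent cross-check of the closed-form inversion.
    """

    def __init__(
        self,
        timeline: ScreenTimeline,
        phi_range: tuple[float, float] = (0.25, 2.0),
        n_phi: int = 60,
        d_max_factor: float = 5.0,
        n_d: int = 60,
        growth_constraint=proportional_inhibition,
    ):
        self.timeline = timeline
        self.growth_constraint = growth_constraint
        self.phi_grid = np.geomspace(phi_range[0], phi_range[1], n_phi)
        d_max = d_max_factor * max(timeline.treated_rates.d, 1e-3)
        self.d_grid = np.linspace(0.0, d_max, n_d)
        self.A_grid = np.empty(n_phi)
        self.B_grid = np.empty((n_phi, n_d))
        for i, phi in enumerate(self.phi_grid):
            g_i = growth_constraint(phi, timeline)
            for j, d in enumerate(self.d_grid):
                a, b = predict_l2fc(phi, g_i, d, timeline)
                self.A_grid[i] = a
                self.B_grid[i, j] = b

    def invert(self, A: float, B: float) -> KnockoutInference:
        flag = ""
        # A is strictly increasing in phi
        if A < self.A_grid[0] or A > self.A_grid[-1]:
            flag = "clamped_phi"
            A = float(np.clip(A, self.A_grid[0], self.A_grid[-1]))
        phi = float(np.interp(A, self.A_grid, self.phi_grid))
        i = int(np.clip(np.searchsorted(self.A_grid, A) - 1, 0, len(self.phi_grid) - 2))
        w = (A - self.A_grid[i]) / (self.A_grid[i + 1] - self.A_grid[i])
        b_row = (1 - w) * self.B_grid[i] + w * self.B_grid[i + 1]
        # B is strictly decreasing in d at fixed phi
        b_lo, b_hi = b_row[-1], b_row[0]
        if B > b_hi or B < b_lo:
            flag = (flag + ";" if flag else "") + "clamped_d"
            B = float(np.clip(B, b_lo, b_hi))
        d = float(np.interp(B, b_row[::-1], self.d_grid[::-1]))
        g_i = self.growth_constraint(phi, self.timeline)
        return KnockoutInference(phi=phi, g_i=g_i, d_i=d, flag=flag)


def infer_by_grid(
    A: float, B: float, timeline: ScreenTimeline, grid: MedusaGrid | None = None
) -> KnockoutInference:
    """Grid-lookup inversion (see :class:`MedusaGrid`)."""
    if grid is None:
        grid = MedusaGrid(timeline)
    return grid.invert(A, B)


class MedusaScreen:
    """MEDUSA analysis of a chemo-genetic profile.

    Parameters
    ----------
    counts : CountMatrix
        Guide × sample counts with T0, untreated and treated columns.
    library : GuideLibrary
        Guide annotation including non-targeting flags.
    timeline : ScreenTimeline
        Assay durations plus wild-type rates in both arms.
    drug : str, optional
        Restrict the treated contrast to one drug label.
    filter_quantile : float
        Low-abundance guide filter (fraction removed by base mean).
    pseudocount : float
        Added to both sides of every L2FC.
    group_size : int
        Non-targeting pseudo-gene size.
    growth_constraint : callable
        (phi, timeline) -> g_i; closes the (g_i, d_i) degeneracy.
    """

    def __init__(
        self,
        counts: CountMatrix,
        library: GuideLibrary,
        timeline: ScreenTimeline,
        drug: str | None = None,
        filter_quantile: float = 0.05,
        pseudocount: float = 0.5,
        group_size: int = 4,
        growth_constraint=proportional_inhibition,
    ):
        self.counts = counts
        self.library = library
        self.timeline = timeline
        self.drug = drug
        self.filter_quantile = filter_quantile
        self.pseudocount = pseudocount
        self.group_size = group_size
        self.growth_constraint = growth_constraint

    def fit(self, iterations: int = 10_000, seed: int = 0) -> "MedusaResults":
        """Run the full pipeline; all randomness is driven by ``seed``."""
        rng = np.random.default_rng(seed)
        filtered, dropped = _stats.filter_low_abundance(
            self.counts.counts, self.filter_quantile
        )
        norm = _stats.normalize_size_factors(filtered)
        samples = self.counts.samples
        A = _stats.guide_l2fc(norm, samples, _stats.CONTRASTS["essentiality"],
                              self.pseudocount)
        B = _stats.guide_l2fc(norm, samples, _stats.CONTRASTS["treated_vs_untreated"],
                              self.pseudocount, drug=self.drug)
        cond = _stats.guide_l2fc(norm, samples,
                                 _stats.CONTRASTS["conditional_essentiality"],
                                 self.pseudocount, drug=self.drug)

        records = []
        for gid in filtered.index:
            inf = infer_knockout_rates(float(A.loc[gid]), float(B.loc[gid]),
                                       self.timeline, self.growth_constraint)
            records.append((gid, inf.phi, inf.g_i, inf.d_i, inf.residual, inf.flag))
        guide_table = pd.DataFrame(
            records,
            columns=["guide_id", "phi", "g_i", "d_i", "residual", "flag"],
        ).set_index("guide_id")
        guide_table["l2fc_A"] = A
        guide_table["l2fc_B"] = B
        guide_table["l2fc_conditional"] = cond

        pseudo = _stats.make_nt_pseudogenes(self.library, self.group_size, rng)
        death = _stats.gene_stat_table(
            guide_table["d_i"], self.library, pseudo, method="mean",
            iterations=iterations, seed=rng, contrast="medusa_death_rate",
        )
        growth = _stats.gene_stat_table(
            guide_table["g_i"], self.library, pseudo, method="mean",
            iterations=iterations, seed=rng, contrast="medusa_growth_rate",
        )
        return MedusaResults(
            self, guide_table, death, growth, dropped_guides=dropped, seed=seed
        )


class MedusaResults:
    """Per-guide inferences and per-gene death/growth tables.

    ``gene_death`` and ``gene_growth`` are indexed by gene with columns
    score (mean inferred rate), z, p, q, n_guides.  Metadata records the
    growth constraint used to break the (g_i, d_i) degeneracy.
    """

    def __init__(self, model, guide_table, gene_death, gene_growth,
                 dropped_guides, seed):
        self.model = model
        self.guide_table = guide_table
        self.gene_death = gene_death
        self.gene_growth = gene_growth
        self.dropped_guides = dropped_guides
        self.seed = seed
        self.metadata = {
            "growth_constraint": getattr(model.growth_constraint, "__name__",
                                         repr(model.growth_constraint)),
            "t_treat_h": model.timeline.t_treat,
            "t_untreat_h": model.timeline.t_untreat,
            "filter_quantile": model.filter_quantile,
            "pseudocount": model.pseudocount,
            "seed": seed,
        }

    def hits(self, axis: str = "death", q_threshold: float = 0.05) -> pd.Index:
        """Genes whose rate differs from the non-targeting null at q < thr."""
        table = self.gene_death if axis == "death" else self.gene_growth
        real = table[~table["is_nontargeting"]]
        return real.index[real["q"] < q_threshold]

    def summary(self) -> str:
        n_death = len(self.hits("death"))
        n_growth = len(self.hits("growth"))
        lines = [
            "MEDUSA chemo-genetic screen analysis",
            f"  guides analysed: {len(self.guide_table)} "
            f"({len(self.dropped_guides)} removed by abundance filter)",
            f"  growth constraint: {self.metadata['growth_constraint']}",
            f"  treated window: {self.model.timeline.t_treat:g} h; "
            f"untreated window: {self.model.timeline.t_untreat:g} h",
            f"  death-rate hits (q<0.05): {n_death}",
            f"  growth-rate hits (q<0.05): {n_growth}",
        ]
        return "\n".join(lines)

    def plot_volcano(self, axis: str = "death", ax=None):
        import matplotlib.pyplot as plt

        table = self.gene_death if axis == "death" else self.gene_growth
        if ax is None:
            _, ax = plt.subplots()
        real = table[~table["is_nontargeting"]]
        nt = table[table["is_nontargeting"]]
        ax.scatter(real["z"], -np.log10(real["q"]), s=4, alpha=0.5)
        ax.scatter(nt["z"], -np.log10(nt["q"]), s=6, color="dimgray")
        ax.set_xlabel(f"{axis}-rate z score")
        ax.set_ylabel("-log10 q")
        return ax
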
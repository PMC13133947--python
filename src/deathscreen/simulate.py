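"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline's three data sources:

* :func:`simulate_flick_plate` — live/dead trajectories from the
  birth-death model rendered as plate fluorescence (T0-lysed, kinetic
  dead-cell and endpoint-lysed readings) with multiplicative lognormal
  noise;
* :func:`simulate_screen` — a pooled knockout screen: per-gene growth
  multipliers and drug-induced death rates, per-guide efficacy jitter,
  clone abundances evolved through treated/untreated arms, and multinomial
  sequencing at a stated depth;
* :func:`simulate_dose_matrix` — two-drug response surfaces built under a
  named reference model (Loewe, Bliss, or Loewe with a potency-shift
  synergy) for both FV and RV readouts.

Every generator is driven by a single integer seed and is bit-reproducible.

Default screen conditions: 1,000 genes x 4 guides plus 142 non-targeting
guides; 5% death-suppressors, 5% death-sensitizers, 10% growth-only, 10%
essential genes; 500x sequencing coverage; 2 replicates per arm; lognormal
guide-efficacy jitter with sd 0.1.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import NONTARGETING_GENE, CountMatrix, GuideLibrary
from .medusa import ScreenTimeline, proportional_inhibition
from .rates import LN2, RatePair, simulate_live_dead
from .synergy import DoseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenTruth",
    "make_screen_truth",
    "random_guide_library",
    "simulate_flick_plate",
    "simulate_screen",
    "simulate_dose_matrix",
    "DEFAULT_CLASS_FRACTIONS",
]

GENE_CLASSES = ("null", "death_suppressor", "death_sensitizer", "growth_only", "essential")
DEFAULT_CLASS_FRACTIONS = {
    "death_suppressor": 0.05,
    "death_sensitizer": 0.05,
    "growth_only": 0.10,
    "essential": 0.10,
}


@dataclass
class ScreenTruth:
    """Ground truth of a synthetic screen.

    ``genes``: frame indexed by gene with columns class, phi (untreated
    growth multiplier) and d_i (treated death rate, /h).  ``guides``:
    frame indexed by guide_id with gene, per-guide phi and d_i after
    efficacy jitter.
    """

    genes: pd.DataFrame
    guides: pd.DataFrame
    seed: int
    depth_coverage: float
    replicates: int


def _random_sequences(n: int, length: int, rng: np.random.Generator) -> list[str]:
    seqs: set[str] = set()
    bases = np.array(list("ACGT"))
    while len(seqs) < n:
        batch = rng.integers(0, 4, size=(n, length))
        for row in batch:
            seqs.add("".join(bases[row]))
            if len(seqs) == n:
                break
    return sorted(seqs)


def random_guide_library(
    n_genes: int = 1000,
    guides_per_gene: int = 4,
    n_nontargeting: int = 142,
    guide_length: int = 20,
    seed: int = 0,
) -> GuideLibrary:
    """Synthetic guide library in the screen library shape."""
    rng = np.random.default_rng(seed)
    n_guides = n_genes * guides_per_gene + n_nontargeting
    seqs = _random_sequences(n_guides, guide_length, rng)
    rng.shuffle(seqs)
    rows = []
    k = 0
    for gi in range(n_genes):
        gene = f"GENE{gi + 1:04d}"
        for j in range(guides_per_gene):
            rows.append((f"{gene}_g{j + 1}", seqs[k], gene, False))
            k += 1
    for j in range(n_nontargeting):
        rows.append((f"NT_{j + 1:03d}", seqs[k], NONTARGETING_GENE, True))
        k += 1
    return GuideLibrary(pd.DataFrame(rows, columns=["guide_id", "sequence", "gene",
                                                    "is_nontargeting"]))


def make_screen_truth(
    library: GuideLibrary,
    timeline: ScreenTimeline,
    class_fractions: dict[str, float] | None = None,
    efficacy_jitter_sd: float = 0.1,
    depth_coverage: float = 500.0,
    replicates: int = 2,
    seed: int = 0,
) -> ScreenTruth:
    """Assign gene classes and true rates to a guide library.

    Class effects (relative to wild type with untreated rates (g0, d0) and
    treated rates (gT, dT)); effect sizes are graded — drawn per gene from
    a range — since knockout phenotypes vary in strength:

    ==================  ===========  ==================================
    class               phi          treated death rate d_i
    ==================  ===========  ==================================
    null                1            dT
    death_suppressor    1            uniform(d0, 0.5*dT) (death rescued)
    death_sensitizer    1            uniform(1.5, 3.5) * dT
    growth_only         0.5 - 0.9    dT (death untouched)
    essential           0.4 - 0.6    dT
    ==================  ===========  ==================================

    Per-guide efficacy jitter multiplies each guide's deviation from wild
    type by a lognormal factor (sd ``efficacy_jitter_sd``), so the four
    guides of a gene scatter around the gene effect.
    """
    rng = np.random.default_rng(seed)
    fr = dict(DEFAULT_CLASS_FRACTIONS if class_fractions is None else class_fractions)
    genes = sorted(set(library.table.loc[~library.table["is_nontargeting"], "gene"]))
    n = len(genes)
    order = rng.permutation(n)
    labels = np.array(["null"] * n, dtype=object)
    start = 0
    for cls in ("death_suppressor", "death_sensitizer", "growth_only", "essential"):
        cnt = int(round(fr.get(cls, 0.0) * n))
        labels[order[start:start + cnt]] = cls
        start += cnt

    d0 = timeline.untreated_rates.d
    dT = timeline.treated_rates.d
    phi = np.ones(n)
    d_i = np.full(n, dT)
    for idx, cls in enumerate(labels):
        if cls == "death_suppressor":
            d_i[idx] = rng.uniform(d0, 0.5 * dT)
        elif cls == "death_sensitizer":
            d_i[idx] = rng.uniform(1.5, 3.5) * dT
        elif cls == "growth_only":
            phi[idx] = rng.uniform(0.5, 0.9)
        elif cls == "essential":
            phi[idx] = rng.uniform(0.4, 0.6)
    gene_df = pd.DataFrame({"class": labels, "phi": phi, "d_i": d_i},
                           index=pd.Index(genes, name="gene"))

    tbl = library.table
    guide_rows = []
    for row in tbl.itertuples():
        if row.is_nontargeting:
            guide_rows.append((row.guide_id, NONTARGETING_GENE, 1.0, dT))
            continue
        g = gene_df.loc[row.gene]
        jitter = rng.lognormal(0.0, efficacy_jitter_sd)
        gphi = 1.0 + (g["phi"] - 1.0) * jitter
        gd = max(dT + (g["d_i"] - dT) * jitter, 0.0)
        guide_rows.append((row.guide_id, row.gene, gphi, gd))
    guide_df = pd.DataFrame(
        guide_rows, columns=["guide_id", "gene", "phi", "d_i"]
    ).set_index("guide_id")
    return ScreenTruth(genes=gene_df, guides=guide_df, seed=seed,
                       depth_coverage=depth_coverage, replicates=replicates)


def simulate_screen(
    truth: ScreenTruth,
    library: GuideLibrary,
    timeline: ScreenTimeline,
    expectation_mode: bool = False,
    dispersion: float = 0.0,
    seed: int = 0,
) -> CountMatrix:
    """Evolve clone abundances through both arms and sequence them.

    Initial clone abundances are lognormally scattered (library prep);
    each arm multiplies clone i's abundance by ``exp(k_i * t)`` with
    ``k_i`` from the live-cell birth-death model, the treated growth rate
    following the proportional-inhibition relation ``g_i = phi * gT``.
    Reads per sample are multinomial at ``depth_coverage x n_guides``
    total reads (``expectation_mode`` replaces sampling by the rounded
    expected counts; ``dispersion`` > 0 adds gamma overdispersion on the
    clone weights before sampling).
    """
    rng = np.random.default_rng(seed)
    guides = truth.guides
    n = len(guides)
    max_frac_warn = 0.01

    p0 = rng.lognormal(0.0, 0.2, size=n)
    p0 /= p0.sum()
    if p0.max() > max_frac_warn:
        warnings.warn("a clone exceeds 1% of the library at T0; the "
                      "infinitesimal-clone approximation may be strained",
                      stacklevel=2)

    g0 = timeline.untreated_rates.g
    d0 = timeline.untreated_rates.d
    gT = timeline.treated_rates.g
    phi = guides["phi"].to_numpy()
    d_i = guides["d_i"].to_numpy()
    k_u = phi * g0 * LN2 - d0
    k_t = phi * gT * LN2 - d_i

    w_u = p0 * np.exp(k_u * timeline.t_untreat)
    w_t = p0 * np.exp(k_t * timeline.t_treat)

    depth = int(round(truth.depth_coverage * n))
    cols, names, meta = [], [], []

    def _sample(weights: np.ndarray) -> np.ndarray:
        p = weights / weights.sum()
        if dispersion > 0:
            p = rng.gamma(1.0 / dispersion, p * dispersion)
            p /= p.sum()
        if expectation_mode:
            return np.round(p * depth).astype(np.int64)
        return rng.multinomial(depth, p)

    cols.append(_sample(p0)); names.append("T0"); meta.append(("T0", "", 1))
    for r in range(1, truth.replicates + 1):
        cols.append(_sample(w_u)); names.append(f"untreated_r{r}")
        meta.append(("untreated", "", r))
    for r in range(1, truth.replicates + 1):
        cols.append(_sample(w_t)); names.append(f"treated_r{r}")
        meta.append(("treated", "drug", r))

    counts = pd.DataFrame(np.column_stack(cols), index=guides.index, columns=names)
    samples = pd.DataFrame(meta, columns=["condition", "drug", "replicate"],
                           index=pd.Index(names, name="sample"))
    if not expectation_mode and depth < 50 * n:
        warnings.warn(f"sequencing depth {depth} is under 50x library size; "
                      "counts will be noisy", stacklevel=2)
    return CountMatrix(counts=counts, samples=samples)


def simulate_flick_plate(
    conditions: list[dict],
    timepoints,
    noise_cv: float = 0.05,
    n_cells_0: float = 2000.0,
    gain: float = 1.0,
    replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Render birth-death trajectories as a tidy plate fluorescence table.

    ``conditions`` is a list of dicts with keys ``drug``, ``dose`` and
    ``rates`` (a RatePair); ``timepoints`` are hours.  Emits, per
    condition and replicate: kinetic dead-cell readings at every
    timepoint, an endpoint-lysed (total) reading at the final timepoint,
    plus shared T0-lysed readings.  Fluorescence = cell equivalents x
    gain x lognormal(1, noise_cv).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    timepoints = sorted(float(t) for t in timepoints)
    t_end = timepoints[-1]
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0

    def _noisy(value: float) -> float:
        f = rng.lognormal(0.0, sigma) if sigma > 0 else 1.0
        return value * gain * f

    rows = []
    for rep in range(1, replicates + 1):
        rows.append({"well": f"T0_r{rep}", "drug": "", "dose": 0.0,
                     "cotreatment": "", "timepoint": 0.0, "kind": "T0_lysed",
                     "fluorescence": _noisy(n_cells_0), "replicate": rep})
    for ci, cond in enumerate(conditions):
        rates: RatePair = cond["rates"]
        drug = cond.get("drug", "drug")
        dose = float(cond.get("dose", 0.0))
        for rep in range(1, replicates + 1):
            well = f"c{ci}_r{rep}"
            for t in timepoints:
                s = simulate_live_dead(n_cells_0, 0.0, rates, t)
                rows.append({"well": well, "drug": drug, "dose": dose,
                             "cotreatment": cond.get("cotreatment", ""),
                             "timepoint": t, "kind": "dead_kinetic",
                             "fluorescence": _noisy(s.D), "replicate": rep})
            s_end = simulate_live_dead(n_cells_0, 0.0, rates, t_end)
            rows.append({"well": well, "drug": drug, "dose": dose,
                         "cotreatment": cond.get("cotreatment", ""),
                         "timepoint": t_end, "kind": "endpoint_lysed",
                         "fluorescence": _noisy(s_end.L + s_end.D), "replicate": rep})
    return pd.DataFrame(rows)


def _hill_fa(d: np.ndarray, m: float, dm: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        out = 1.0 / (1.0 + (dm / np.where(d > 0, d, np.nan)) ** m)
    return np.where(d > 0, out, 0.0)


def _loewe_fa(d1, d2, m1, dm1, m2, dm2):
    """Additive combined affected fraction solving the Loewe sum."""
    if d1 == 0 and d2 == 0:
        return 0.0
    if d1 == 0:
        return float(_hill_fa(np.array([d2]), m2, dm2)[0])
    if d2 == 0:
        return float(_hill_fa(np.array([d1]), m1, dm1)[0])

    def gap(x):
        dx1 = dm1 * (x / (1 - x)) ** (1 / m1)
        dx2 = dm2 * (x / (1 - x)) ** (1 / m2)
        return d1 / dx1 + d2 / dx2 - 1.0

    return brentq(gap, 1e-12, 1 - 1e-12)


def simulate_dose_matrix(
    doses1,
    doses2,
    hill1: tuple[float, float] = (2.0, 1.0),
    hill2: tuple[float, float] = (2.0, 1.0),
    interaction: str = "loewe",
    kappa: float = 1.0,
    rv_hill1: tuple[float, float] | None = None,
    rv_hill2: tuple[float, float] | None = None,
    rv_interaction: str | None = None,
    rv_kappa: float | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[DoseMatrix, dict]:
    """Construct FV and RV surfaces under a named reference model.

    ``hill*`` are (slope m, median-effect dose Dm) for the death effect
    (1 - FV); ``rv_hill*`` default to the same for the growth effect
    (1 - RV).  ``interaction``: ``loewe`` (dose-additive), ``bliss``
    (probabilistically independent) or ``synergy`` (Loewe surface with
    combination doses potency-shifted by ``kappa``, so the combo reaches
    any level at 1/kappa of the additive dose; the single-agent margins
    are untouched).  The RV surface takes its own interaction (defaults
    to the FV one).  Returns (DoseMatrix, truth dict).
    """
    if interaction not in ("loewe", "bliss", "synergy"):
        raise ValueError(f"unknown interaction model {interaction!r}")
    rng = np.random.default_rng(seed)
    doses1 = np.asarray(doses1, dtype=float)
    doses2 = np.asarray(doses2, dtype=float)
    rv_hill1 = hill1 if rv_hill1 is None else rv_hill1
    rv_hill2 = hill2 if rv_hill2 is None else rv_hill2
    rv_interaction = interaction if rv_interaction is None else rv_interaction
    if rv_interaction not in ("loewe", "bliss", "synergy"):
        raise ValueError(f"unknown interaction model {rv_interaction!r}")
    rv_kappa = kappa if rv_kappa is None else rv_kappa

    def surface(h1, h2, model, kap):
        m1, dm1 = h1
        m2, dm2 = h2
        fa = np.zeros((len(doses1), len(doses2)))
        for i, d1 in enumerate(doses1):
            for j, d2 in enumerate(doses2):
                if model == "bliss":
                    f1 = float(_hill_fa(np.array([d1]), m1, dm1)[0]) if d1 > 0 else 0.0
                    f2 = float(_hill_fa(np.array([d2]), m2, dm2)[0]) if d2 > 0 else 0.0
                    fa[i, j] = f1 + f2 - f1 * f2
                else:
                    scale = kap if (model == "synergy" and d1 > 0 and d2 > 0) else 1.0
                    fa[i, j] = _loewe_fa(scale * d1, scale * d2, m1, dm1, m2, dm2)
        return fa

    fa_death = surface(hill1, hill2, interaction, kappa)
    fa_growth = surface(rv_hill1, rv_hill2, rv_interaction, rv_kappa)
    fv = 1.0 - fa_death
    rv = 1.0 - fa_growth
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        fv = np.clip(fv * rng.lognormal(0.0, sigma, fv.shape), 0.0, 1.0)
        rv = np.clip(rv * rng.lognormal(0.0, sigma, rv.shape), 0.0, None)
    truth = {
        "interaction": interaction, "kappa": kappa,
        "rv_interaction": rv_interaction, "rv_kappa": rv_kappa,
        "hill1": hill1, "hill2": hill2,
        "rv_hill1": rv_hill1, "rv_hill2": rv_hill2,
        "noise_cv": noise_cv, "seed": seed,
    }
    return DoseMatrix(doses1, doses2, fv, rv), truth
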
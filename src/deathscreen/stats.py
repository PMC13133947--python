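"""Conventional chemo-genetic screen statistics.

The conventional pipeline: filter low-abundance guides, normalize counts by
median-of-ratios size factors, compute guide-level log2 fold changes for
three contrasts (treated vs untreated; untreated vs T0 "essentiality";
treated vs T0 "conditional essentiality"), collapse guides to genes,
z-score gene scores against a null of non-targeting pseudo-genes, attach
bootstrap empirical p values and Benjamini-Hochberg q values.

Non-targeting guides carry the null: they are randomly partitioned into
pseudo-genes of the same guide multiplicity as real genes, so that the
gene-level null distribution inherits collapse-induced variance shrinkage.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, GuideLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "filter_low_abundance",
    "normalize_size_factors",
    "size_factors",
    "guide_l2fc",
    "make_nt_pseudogenes",
    "collapse_to_gene",
    "zscore_vs_nontargeting",
    "empirical_p",
    "bh_fdr",
    "fisher_overlap",
    "roc_gene_set",
    "gene_stat_table",
]

CONTRASTS = {
    "treated_vs_untreated": ("treated", "untreated"),
    "essentiality": ("untreated", "T0"),
    "conditional_essentiality": ("treated", "T0"),
}


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Per sample: median over guides of count / per-guide geometric mean,
    excluding guides whose geometric mean is zero.  Falls back to
    total-count scaling (factors proportional to column sums, geometric
    mean 1) when no guide is nonzero in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    finite = np.isfinite(logs).all(axis=1)
    if not finite.any():
        warnings.warn(
            "no guide has nonzero counts in all samples; "
            "falling back to total-count size factors",
            stacklevel=2,
        )
        totals = mat.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(factors, index=counts.columns, name="size_factor")
    log_geomean = logs[finite].mean(axis=1)
    ratios = logs[finite] - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_size_factors(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts divided by their median-of-ratios size factors."""
    return counts / size_factors(counts)


def filter_low_abundance(
    counts: pd.DataFrame, quantile: float = 0.05
) -> tuple[pd.DataFrame, pd.Index]:
    """Drop the bottom ``quantile`` of guides by base mean.

    Base mean is the mean normalized count across all samples.  Exactly
    ``ceil(quantile * n)`` guides are removed; base-mean ties are broken by
    guide_id lexical order so the cut is deterministic.

    Returns the filtered counts and the index of removed guides.
    """
    if not (0.0 <= quantile < 1.0):
        raise ValueError("quantile must lie in [0, 1)")
    if counts.empty:
        raise ValueError("counts table is empty")
    if quantile == 0.0:
        return counts, pd.Index([], name=counts.index.name)
    base_mean = normalize_size_factors(counts).mean(axis=1)
    # stable sort after a guide_id pre-sort gives the lexical tie-break
    order = base_mean.loc[sorted(base_mean.index)].sort_values(kind="mergesort")
    n_drop = int(np.ceil(quantile * len(counts)))
    dropped = order.index[:n_drop]
    kept = counts.drop(index=dropped)
    logger.info("abundance filter removed %d/%d guides", n_drop, len(counts))
    return kept, pd.Index(dropped)


def guide_l2fc(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: tuple[str, str],
    pseudocount: float = 0.5,
    drug: str | None = None,
) -> pd.Series:
    """Guide-level log2 fold change between two conditions.

    Replicates are averaged per condition on normalized counts, then
    ``log2((mean_num + pc) / (mean_den + pc))``.
    """
    num_cond, den_cond = contrast
    cols = {}
    for cond in (num_cond, den_cond):
        mask = samples["condition"] == cond
        if drug is not None and cond == "treated":
            mask &= samples["drug"] == drug
        cc = [c for c in normalized.columns if c in samples.index[mask]]
        if not cc:
            raise ValueError(f"no samples for condition {cond!r}")
        cols[cond] = cc
    mean_num = normalized[cols[num_cond]].mean(axis=1)
    mean_den = normalized[cols[den_cond]].mean(axis=1)
    l2fc = np.log2((mean_num + pseudocount) / (mean_den + pseudocount))
    l2fc.name = f"l2fc_{num_cond}_vs_{den_cond}"
    return l2fc


def make_nt_pseudogenes(
    library: GuideLibrary,
    group_size: int = 4,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Random partition of non-targeting guides into pseudo-genes.

    Returns guide_id -> pseudo-gene name (``NT_PSEUDO_001`` ...).  Guides
    left over after filling groups of ``group_size`` are unassigned
    (dropped, logged).  Same seed, same assignment.
    """
    nt = library.nontargeting_ids()
    if len(nt) < group_size:
        raise ValueError(
            f"need at least {group_size} non-targeting guides, have {len(nt)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shuffled = list(np.array(sorted(nt))[rng.permutation(len(nt))])
    n_groups = len(nt) // group_size
    mapping = {}
    for i in range(n_groups):
        name = f"NT_PSEUDO_{i + 1:03d}"
        for gid in shuffled[i * group_size: (i + 1) * group_size]:
            mapping[gid] = name
    n_rest = len(nt) - n_groups * group_size
    if n_rest:
        logger.info("%d non-targeting guides left unassigned by the %d-guide partition",
                    n_rest, group_size)
    return pd.Series(mapping, name="pseudo_gene")


def collapse_to_gene(
    guide_scores: pd.Series,
    guide_to_gene: pd.Series,
    method: str = "median",
) -> pd.DataFrame:
    """Collapse guide scores to genes by median or mean.

    Guides without a gene assignment are dropped (logged).  Returns a frame
    indexed by gene with columns ``score`` and ``n_guides``.
    """
    if method not in ("median", "mean"):
        raise ValueError(f"unknown collapse method {method!r}")
    genes = guide_to_gene.reindex(guide_scores.index)
    keep = genes.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("collapse dropped %d guides without gene assignment", n_dropped)
    df = pd.DataFrame({"score": guide_scores[keep], "gene": genes[keep]})
    grouped = df.groupby("gene")["score"]
    out = pd.DataFrame(
        {"score": grouped.median() if method == "median" else grouped.mean(),
         "n_guides": grouped.size()}
    )
    return out


def zscore_vs_nontargeting(
    gene_scores: pd.Series, nt_scores: pd.Series
) -> pd.Series:
    """z = (score - mean_nt) / sd_nt with the sample (n-1) sd."""
    if len(nt_scores) < 2:
        raise ValueError("need >= 2 non-targeting pseudo-gene scores")
    mu = float(nt_scores.mean())
    sd = float(nt_scores.std(ddof=1))
    if sd == 0:
        raise ValueError("non-targeting pseudo-gene scores have zero spread")
    z = (gene_scores - mu) / sd
    z.name = "z"
    return z


def empirical_p(
    gene_z: pd.Series,
    n_guides: pd.Series,
    null_pool: np.ndarray,
    nt_scores: pd.Series,
    method: str = "median",
    iterations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Two-sided bootstrap empirical p value per gene.

    For each gene with n guides, ``iterations`` resamples of n guide-level
    null scores (non-targeting guides, with replacement) are collapsed with
    the same method and z-scored against the non-targeting pseudo-gene
    distribution.  p = (1 + #{|z_null| >= |z_obs|}) / (1 + iterations).
    """
    if iterations < 100:
        warnings.warn("fewer than 100 bootstrap iterations; p values are coarse",
                      stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null_pool = np.asarray(null_pool, dtype=float)
    if null_pool.size == 0:
        raise ValueError("empty null pool")
    mu = float(nt_scores.mean())
    sd = float(nt_scores.std(ddof=1))
    collapse = np.median if method == "median" else np.mean

    abs_null_by_n: dict[int, np.ndarray] = {}
    p = pd.Series(index=gene_z.index, dtype=float, name="p")
    for n in sorted(set(int(x) for x in n_guides.reindex(gene_z.index))):
        draws = rng.choice(null_pool, size=(iterations, n), replace=True)
        z_null = (collapse(draws, axis=1) - mu) / sd
        abs_null_by_n[n] = np.sort(np.abs(z_null))
    for gene in gene_z.index:
        n = int(n_guides.loc[gene])
        sorted_abs = abs_null_by_n[n]
        n_ge = len(sorted_abs) - np.searchsorted(sorted_abs, abs(gene_z.loc[gene]),
                                                 side="left")
        p.loc[gene] = (1 + n_ge) / (1 + iterations)
    return p


def bh_fdr(p: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up q values (monotone-enforced)."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    q = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index, name="q")
    return q


def fisher_overlap(
    set_a: set, set_b: set, universe: set, or_cap: float = np.inf
) -> tuple[float, float, dict]:
    """Fisher's exact test for overlap of two gene sets within a universe.

    Returns (odds_ratio, p, table).  The odds ratio is the sample OR
    ``ad/bc`` with a 0.5 Haldane correction applied only when a cell is
    zero; infinite ORs are capped at ``or_cap`` and flagged in the table
    dict.  p is the two-sided hypergeometric (Fisher exact) p value.
    """
    if not universe:
        raise ValueError("empty universe")
    set_a, set_b = set_a & universe, set_b & universe
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe - set_a - set_b)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    flagged = False
    if min(a, b, c, d) == 0:
        ah, bh_, ch, dh = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        oddsratio = (ah * dh) / (bh_ * ch)
        flagged = True
    else:
        oddsratio = (a * d) / (b * c)
    if not np.isfinite(oddsratio) or oddsratio > or_cap:
        oddsratio = or_cap
        flagged = True
    return float(oddsratio), float(p), {
        "a": a, "b": b, "c": c, "d": d, "haldane_or_capped": flagged,
    }


def roc_gene_set(
    scores: pd.Series,
    positive_set: set,
    bootstrap_iterations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, str]:
    """Rank-based AUC of a positive gene set with a permutation p value.

    AUC measures how well ``scores`` rank ``positive_set`` genes above the
    rest.  The empirical p is the add-one-corrected fraction of
    label-permuted AUCs at least as large as the observed AUC.
    Returns (auc, p, flag).
    """
    labels = scores.index.isin(positive_set).astype(int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("positive set must be a non-empty strict subset")
    vals = scores.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        return 0.5, 1.0, "all_scores_tied"
    auc = float(roc_auc_score(labels, vals))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ge = 0
    for _ in range(bootstrap_iterations):
        perm = rng.permutation(labels)
        if roc_auc_score(perm, vals) >= auc:
            n_ge += 1
    p = (1 + n_ge) / (1 + bootstrap_iterations)
    return auc, float(p), ""


def gene_stat_table(
    guide_scores: pd.Series,
    library: GuideLibrary,
    pseudo_genes: pd.Series,
    method: str = "median",
    iterations: int = 10_000,
    seed: int | np.random.Generator = 0,
    contrast: str = "",
) -> pd.DataFrame:
    """Full gene-level statistics from guide-level scores.

    Collapses real genes and non-targeting pseudo-genes with ``method``,
    z-scores against the pseudo-gene distribution, attaches bootstrap
    empirical p and BH-FDR q.  Returns a frame indexed by gene with columns
    score, z, p, q, n_guides, is_nontargeting, contrast.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g2g = library.guide_to_gene().copy()
    # replace the non-targeting sentinel gene by pseudo-gene labels; NT
    # guides outside the partition drop out of the collapse
    nt_ids = library.nontargeting_ids()
    g2g.loc[nt_ids] = pd.NA
    g2g.update(pseudo_genes)

    collapsed = collapse_to_gene(guide_scores, g2g, method=method)
    is_nt = collapsed.index.str.startswith("NT_PSEUDO_")
    nt_scores = collapsed.loc[is_nt, "score"]
    z = zscore_vs_nontargeting(collapsed["score"], nt_scores)
    null_pool = guide_scores.reindex(nt_ids).dropna().to_numpy()
    p = empirical_p(z, collapsed["n_guides"], null_pool, nt_scores,
                    method=method, iterations=iterations, seed=rng)
    q = bh_fdr(p)
    out = collapsed.assign(z=z, p=p, q=q, is_nontargeting=is_nt)
    out["contrast"] = contrast
    return out.sort_values("z")
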
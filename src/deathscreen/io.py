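"""Readers, writers and guide counting for screen pipeline formats.

Formats handled here:

* guide library TSV — columns ``guide_id, sequence, gene, is_nontargeting``
* counts TSV — guides as rows, samples as columns, first column ``guide_id``
* sample sheet CSV — ``sample, condition, drug, replicate``
* plate CSV — tidy well table (``well, cell_line, drug, dose, cotreatment,
  timepoint, kind, fluorescence``)
* FASTQ — 4-line records; qualities ignored
* YAML config — screen timeline, library flanks, seeds

Guide counting replaces an aligner with an exact / Hamming-distance matcher
over the guide set: a read's guide window is assigned to the unique guide
within ``max_mismatch`` substitutions; ties at the minimal distance are
ambiguous and dropped, and all drops are tallied.
"""

from __future__ import annotations

import gzip
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "GuideLibrary",
    "CountMatrix",
    "read_guide_library",
    "write_guide_library",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "read_plate_table",
    "write_results",
    "load_config",
    "count_guides_from_fastq",
    "CountingSummary",
]

_DNA = set("ACGT")
NONTARGETING_GENE = "NON_TARGETING"


@dataclass(frozen=True)
class GuideLibrary:
    """Validated guide→gene annotation table.

    ``table`` has columns guide_id, sequence, gene, is_nontargeting; guide
    ids and sequences are unique and sequences share one length.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = ["guide_id", "sequence", "gene", "is_nontargeting"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"guide library missing columns: {missing}")
        dup = t["guide_id"][t["guide_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate guide_id: {dup.iloc[0]!r}")
        dup_seq = t["sequence"][t["sequence"].duplicated()]
        if len(dup_seq):
            raise ValueError(f"duplicate guide sequence: {dup_seq.iloc[0]!r}")
        lengths = t["sequence"].str.len().unique()
        if len(lengths) > 1:
            raise ValueError(f"guide sequences have mixed lengths: {sorted(lengths)}")
        for row in t.itertuples():
            if not set(row.sequence) <= _DNA:
                raise ValueError(
                    f"non-ACGT sequence for guide {row.guide_id!r}: {row.sequence!r}"
                )

    @property
    def guide_length(self) -> int:
        return int(self.table["sequence"].str.len().iloc[0])

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.table["guide_id"])

    @property
    def n_nontargeting(self) -> int:
        return int(self.table["is_nontargeting"].sum())

    def guide_to_gene(self) -> pd.Series:
        return self.table.set_index("guide_id")["gene"]

    def nontargeting_ids(self) -> list[str]:
        return self.table.loc[self.table["is_nontargeting"], "guide_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CountMatrix:
    """Guide × sample integer counts with per-sample metadata.

    ``counts``: DataFrame indexed by guide_id, one integer column per
    sample.  ``samples``: DataFrame indexed by sample name with columns
    ``condition`` (T0 / untreated / treated), ``drug`` and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.to_numpy().dtype, np.integer):
            vals = self.counts.to_numpy()
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        extra = set(self.counts.columns) - set(self.samples.index)
        if extra:
            raise ValueError(f"samples sheet missing metadata for: {sorted(extra)}")

    def columns_for(self, condition: str, drug: str | None = None) -> list[str]:
        meta = self.samples
        mask = meta["condition"] == condition
        if drug is not None and condition != "T0":
            mask &= meta["drug"].fillna("").isin([drug, ""])
        cols = [c for c in self.counts.columns if c in meta.index[mask]]
        if not cols:
            raise ValueError(f"no samples with condition {condition!r}")
        return cols


def read_guide_library(path) -> GuideLibrary:
    """Read and validate a guide library TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"guide_id": str, "sequence": str, "gene": str})
    required = ["guide_id", "sequence", "gene", "is_nontargeting"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"guide library {path} missing columns: {missing}")
    df["sequence"] = df["sequence"].str.upper()
    df["is_nontargeting"] = df["is_nontargeting"].astype(bool)
    lib = GuideLibrary(df.reset_index(drop=True))
    logger.info("read guide library %s: %d guides, %d non-targeting",
                path, len(lib), lib.n_nontargeting)
    return lib


def write_guide_library(lib: GuideLibrary, path) -> None:
    lib.table.to_csv(path, sep="\t", index=False)


def read_counts(counts_path, sample_sheet_path) -> CountMatrix:
    """Read a counts TSV plus its sample sheet CSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col="guide_id")
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"negative count in {counts_path}")
    samples = read_sample_sheet(sample_sheet_path)
    return CountMatrix(counts=counts.astype(np.int64), samples=samples)


def write_counts(cm: CountMatrix, counts_path, sample_sheet_path=None) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="guide_id")
    if sample_sheet_path is not None:
        cm.samples.to_csv(sample_sheet_path, index_label="sample")


def read_sample_sheet(path) -> pd.DataFrame:
    samples = pd.read_csv(path, index_col="sample")
    required = {"condition", "drug", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {sorted(missing)}")
    bad = set(samples["condition"]) - {"T0", "untreated", "treated"}
    if bad:
        raise ValueError(f"unknown conditions in sample sheet: {sorted(bad)}")
    return samples


_PLATE_KINDS = {"dead_kinetic", "endpoint_lysed", "T0_lysed"}


def read_plate_table(path) -> pd.DataFrame:
    """Read a tidy plate fluorescence CSV and validate its schema."""
    df = pd.read_csv(path)
    required = {"drug", "dose", "timepoint", "kind", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate table {path} missing columns: {sorted(missing)}")
    bad = set(df["kind"]) - _PLATE_KINDS
    if bad:
        raise ValueError(f"unknown reading kinds: {sorted(bad)}")
    if (df["fluorescence"] < 0).any():
        raise ValueError("fluorescence must be non-negative")
    return df


def write_results(results: pd.DataFrame, path) -> None:
    """Write an analysis results table as TSV."""
    results.to_csv(path, sep="\t", index=False)


_REQUIRED_CONFIG_BLOCKS = ("timeline",)


def load_config(path) -> dict:
    """Load a YAML run configuration.

    Required block: ``timeline`` (t_treat, t_untreat, untreated/treated
    rates).  Optional blocks: ``library`` (flank5, flank3, max_mismatch),
    ``stats`` (seed, iterations, fdr_threshold), ``logging``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    for block in _REQUIRED_CONFIG_BLOCKS:
        if block not in cfg:
            raise ValueError(f"config {path} missing required block: {block!r}")
    return cfg


@dataclass
class CountingSummary:
    """Read-assignment tally from one FASTQ counting pass."""

    total: int = 0
    assigned: int = 0
    ambiguous: int = 0
    unassigned: int = 0

    def check(self) -> None:
        assert self.total == self.assigned + self.ambiguous + self.unassigned


_AMBIGUOUS = object()


def _mismatch_index(sequences: list[str], guide_ids: list[str], max_mismatch: int):
    """Map every sequence within max_mismatch of a guide to that guide.

    Variants reachable from more than one guide map to an ambiguity
    sentinel.  Exact sequences always win over mismatch variants.
    """
    exact = dict(zip(sequences, guide_ids))
    if max_mismatch == 0:
        return exact, {}
    near: dict[str, object] = {}
    alphabet = "ACGT"
    for seq, gid in zip(sequences, guide_ids):
        for pos in range(len(seq)):
            orig = seq[pos]
            for base in alphabet:
                if base == orig:
                    continue
                variant = seq[:pos] + base + seq[pos + 1:]
                if variant in near and near[variant] != gid:
                    near[variant] = _AMBIGUOUS
                else:
                    near[variant] = gid
    return exact, near


def _iter_fastq(handle):
    """Yield read sequences from a 4-line-record FASTQ handle."""
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline().rstrip("\n")
        handle.readline()  # +
        handle.readline()  # qualities
        yield seq


def count_guides_from_fastq(
    reads,
    library: GuideLibrary,
    max_mismatch: int = 1,
    flank5: str = "",
    sample: str = "sample",
) -> tuple[pd.Series, CountingSummary]:
    """Count one sample's reads against a guide library.

    Parameters
    ----------
    reads : path, file handle or iterable of read sequences
        FASTQ input; a ``.gz`` path is opened transparently.
    max_mismatch : int
        Hamming-distance tolerance (0 or 1 supported; the screen mapping
        convention is a single mismatch).
    flank5 : str
        Constant vector sequence preceding the guide; the guide window is
        the ``guide_length`` bases after its first occurrence.  Empty means
        the read starts at the guide.

    Returns
    -------
    counts : pd.Series indexed by guide_id
    summary : CountingSummary
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    L = library.guide_length
    seqs = library.table["sequence"].tolist()
    ids = library.table["guide_id"].tolist()
    exact, near = _mismatch_index(seqs, ids, max_mismatch)

    close = None
    if isinstance(reads, (str, Path)):
        p = Path(reads)
        handle = gzip.open(p, "rt") if p.suffix == ".gz" else open(p)
        close = handle
        read_iter = _iter_fastq(handle)
    elif hasattr(reads, "readline"):
        read_iter = _iter_fastq(reads)
    else:
        read_iter = iter(reads)

    counts = dict.fromkeys(ids, 0)
    summary = CountingSummary()
    try:
        for read in read_iter:
            summary.total += 1
            read = read.strip().upper()
            if flank5:
                idx = read.find(flank5)
                window = read[idx + len(flank5): idx + len(flank5) + L] if idx >= 0 else ""
            else:
                window = read[:L]
            if len(window) != L:
                summary.unassigned += 1
                continue
            gid = exact.get(window)
            if gid is None:
                gid = near.get(window)
            if gid is None:
                summary.unassigned += 1
            elif gid is _AMBIGUOUS:
                summary.ambiguous += 1
            else:
                counts[gid] += 1
                summary.assigned += 1
    finally:
        if close is not None:
            close.close()

    if summary.total == 0:
        logger.warning("empty read stream for sample %s", sample)
    summary.check()
    logger.info(
        "counted %s: %d reads, %d assigned, %d ambiguous, %d unassigned",
        sample, summary.total, summary.assigned, summary.ambiguous, summary.unassigned,
    )
    return pd.Series(counts, name=sample), summary
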
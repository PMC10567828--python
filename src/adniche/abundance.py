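"""ASV count tables: I/O, rarefaction, absolute abundances and diversity.

The central container is :class:`AsvTable`, a thin wrapper around a pandas
DataFrame (taxa as rows, samples as columns) with a ``mode`` flag tracking
what the numbers mean:

``raw``       integer read counts straight from denoising
``rarefied``  integer counts subsampled without replacement to equal depth
``relative``  percentages (columns sum to 100)
``absolute``  16S copies mL^-1 (relative abundance weighted by a qPCR
              estimate of total community size)

Alpha diversity (richness, Pielou evenness), Bray-Curtis dissimilarity and
the rank-based ANOSIM permutation test operate on these tables.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .errors import (
    EmptyTableError,
    FormatError,
    InvalidGroupingError,
    InvalidInputError,
    MissingMetadataError,
    UndefinedPairError,
)

logger = logging.getLogger(__name__)

MODES = ("raw", "rarefied", "relative", "absolute")


@dataclass
class AsvTable:
    """Taxa-by-samples abundance matrix with a semantic mode flag."""

    data: pd.DataFrame
    mode: str = "raw"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InvalidInputError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise InvalidInputError(f"duplicate taxon id {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise InvalidInputError(f"duplicate sample id {dup!r}")
        if (self.data.to_numpy() < 0).any():
            raise InvalidInputError("counts must be non-negative")
        if self.mode in ("raw", "rarefied"):
            arr = self.data.to_numpy()
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise InvalidInputError(f"{self.mode} tables must hold integers")
                self.data = self.data.round().astype(np.int64)
        if self.mode == "relative":
            sums = self.data.sum(axis=0).to_numpy()
            if not np.allclose(sums, 100.0, atol=1e-6):
                raise InvalidInputError("relative-mode columns must sum to 100")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, samples: Sequence[str]) -> "AsvTable":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise MissingMetadataError(f"unknown samples {missing}")
        return AsvTable(self.data[list(samples)].copy(), mode=self.mode)


def read_count_table(path) -> AsvTable:
    """Read a TSV count table (first column taxon ids, header sample ids).

    Raises :class:`FormatError` naming the offending 1-based line for
    ragged rows, non-integer cells and duplicate identifiers.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: line 1: empty file") from None
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError(f"{path}: line 1: duplicate sample id")
        taxa: list[str] = []
        rows: list[list[int]] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and row[0] == ""):
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            taxon = row[0]
            if taxon in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate taxon id {taxon!r}")
            seen.add(taxon)
            cells: list[int] = []
            for cell in row[1:]:
                try:
                    cells.append(int(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: non-integer cell {cell!r}"
                    ) from None
            taxa.append(taxon)
            rows.append(cells)
    data = pd.DataFrame(rows, index=taxa, columns=sample_ids, dtype=np.int64)
    return AsvTable(data, mode="raw")


def write_count_table(table: AsvTable, path) -> None:
    """Write a table as TSV in the canonical format read_count_table reads."""
    df = table.data
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["taxon_id", *df.columns])
        for taxon, row in df.iterrows():
            writer.writerow([taxon, *row.tolist()])


def rarefy(table: AsvTable, depth: int = 15000, seed: int = 0) -> AsvTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Each retained column is a multivariate-hypergeometric draw from its
    counts and sums exactly to ``depth``.  Samples with fewer than ``depth``
    total reads are dropped with a logged warning.
    """
    if depth < 1:
        raise InvalidInputError(f"depth must be >= 1, got {depth}")
    if table.mode != "raw":
        raise InvalidInputError(f"rarefy expects a raw table, got mode {table.mode!r}")
    rng = np.random.default_rng(seed)
    kept: dict[str, np.ndarray] = {}
    for sample in table.samples:
        counts = table.data[sample].to_numpy(dtype=np.int64)
        total = int(counts.sum())
        if total < depth:
            logger.warning(
                "rarefy: dropping sample %s (%d reads < depth %d)", sample, total, depth
            )
            continue
        if total == depth:
            kept[sample] = counts.copy()
        else:
            kept[sample] = rng.multivariate_hypergeometric(counts, depth)
    if not kept:
        raise EmptyTableError(f"all samples have fewer than {depth} reads")
    data = pd.DataFrame(kept, index=table.taxa, dtype=np.int64)
    return AsvTable(data, mode="rarefied")


def to_relative(table: AsvTable) -> AsvTable:
    """Convert counts to percentages (columns sum to 100)."""
    sums = table.data.sum(axis=0)
    if (sums == 0).any():
        bad = sums.index[sums == 0][0]
        raise InvalidInputError(f"sample {bad!r} has zero total; cannot normalise")
    rel = table.data.astype(float).div(sums, axis=1) * 100.0
    return AsvTable(rel, mode="relative")


def weight_to_absolute(table: AsvTable, copies: Mapping[str, float]) -> AsvTable:
    """Weight relative abundances by per-sample 16S copies mL^-1.

    Columns are converted to percentages and multiplied by ``copies/100``,
    so each column sums to that sample's total community size.
    """
    if table.mode != "rarefied":
        raise InvalidInputError(
            f"weight_to_absolute expects a rarefied table, got mode {table.mode!r}"
        )
    missing = [s for s in table.samples if s not in copies]
    if missing:
        raise MissingMetadataError(f"no copies_per_ml for samples {missing}")
    bad = [s for s in table.samples if copies[s] < 0]
    if bad:
        raise InvalidInputError(f"negative copies_per_ml for samples {bad}")
    rel = to_relative(table)
    scale = pd.Series({s: copies[s] / 100.0 for s in table.samples})
    absolute = rel.data.mul(scale, axis=1)
    return AsvTable(absolute, mode="absolute")


def alpha_diversity(column: np.ndarray | pd.Series) -> tuple[int, float]:
    """Richness S and Pielou evenness J of one abundance vector.

    J = H'/ln(S) with Shannon H' on proportions (natural log); returned as
    NaN when S = 1 (undefined, not zero).
    """
    vec = np.asarray(column, dtype=float)
    if (vec < 0).any():
        raise InvalidInputError("abundances must be non-negative")
    if vec.sum() == 0:
        raise InvalidInputError("all-zero abundance vector")
    present = vec[vec > 0]
    richness = int(present.size)
    if richness == 1:
        return richness, float("nan")
    p = present / present.sum()
    shannon = float(-(p * np.log(p)).sum())
    return richness, shannon / np.log(richness)


def alpha_diversity_table(table: AsvTable) -> pd.DataFrame:
    """Per-sample richness and Pielou evenness as a DataFrame."""
    rows = {}
    for sample in table.samples:
        s, j = alpha_diversity(table.data[sample])
        rows[sample] = {"richness": s, "pielou_evenness": j}
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis_matrix(table: AsvTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples.

    BC(x, y) = sum|x - y| / sum(x + y); symmetric, zero diagonal, in [0, 1].
    """
    if table.mode != "absolute":
        raise InvalidInputError(
            f"bray_curtis_matrix expects an absolute table, got mode {table.mode!r}"
        )
    if len(table.samples) < 2:
        raise InvalidInputError("need at least 2 samples")
    mat = table.data.to_numpy(dtype=float).T  # samples x taxa
    zero = mat.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = [s for s, z in zip(table.samples, zero) if z]
        raise UndefinedPairError(f"Bray-Curtis undefined between all-zero samples {bad}")
    condensed = pdist(mat, metric="braycurtis")
    return pd.DataFrame(squareform(condensed), index=table.samples, columns=table.samples)


@dataclass(frozen=True)
class AnosimResult:
    """Clarke's ANOSIM: R statistic with a permutation p-value."""

    r_statistic: float
    p_value: float
    n_permutations: int
    group_sizes: dict = field(default_factory=dict)


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    n_pairs = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    # Clarke's divisor n(n-1)/4 = (number of pairs)/2
    return float((rb - rw) / (n_pairs / 2.0))


def anosim(
    dist: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Rank-based analysis of similarity.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    with average ranks for ties over all pairwise distances.  The p-value
    counts permutations with R >= observed: (1 + #{>=}) / (1 + n_perm).
    """
    d = np.asarray(dist.values if isinstance(dist, pd.DataFrame) else dist, dtype=float)
    labels = np.asarray(groups)
    n = d.shape[0]
    if d.shape != (n, n) or labels.size != n:
        raise InvalidInputError("distance matrix and groups must agree in size")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise InvalidGroupingError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise InvalidGroupingError(f"singleton groups not allowed: {small}")
    if n_perm < 99:
        raise InvalidInputError(f"n_perm must be >= 99, got {n_perm}")
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])  # average ranks for ties
    within = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranks, within)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        w = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, w) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return AnosimResult(
        r_statistic=r_obs,
        p_value=p,
        n_permutations=n_perm,
        group_sizes={str(u): int(c) for u, c in zip(uniq, counts)},
    )
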
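"""Sensitivity-typed co-occurrence networks from covarying growth.

For each experimental condition (community x medium) the most abundant
taxa are correlated pairwise (Spearman, average ranks for ties) across
that condition's samples.  Edges are the significantly *positive*
correlations after Benjamini-Hochberg adjustment — read as covarying
growth, a proxy for metabolic interaction.  Nodes carry the taxon's
ammonia niche class and methanogen status; clusters are connected
components; network composition is compared with a Pearson chi-square
test on the networks x node-type contingency table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .abundance import AsvTable
from .errors import (
    DegenerateTableError,
    InsufficientSamplesError,
    InvalidInputError,
)
from .niche import bh_adjust

logger = logging.getLogger(__name__)

NODE_TYPES = ("sensitive", "tolerant", "sensitive_methanogen", "tolerant_methanogen")


def top_n_taxa(table: AsvTable, n: int = 1000) -> AsvTable:
    """Retain the n taxa with the largest total abundance.

    Ties at the cut rank are broken lexicographically by taxon id; when
    the table has fewer than n taxa all are retained (logged).
    """
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    totals = table.data.sum(axis=1)
    if len(totals) <= n:
        if len(totals) < n:
            logger.info("top_n_taxa: only %d taxa available (requested %d)", len(totals), n)
        return AsvTable(table.data.copy(), mode=table.mode)
    order = sorted(totals.index, key=lambda t: (-totals[t], t))
    keep = order[:n]
    return AsvTable(table.data.loc[keep].copy(), mode=table.mode)


def spearman_assoc(
    x,
    y,
    method: str = "exact",
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rho with a one-sided (positive) p-value.

    ``exact`` enumerates all n! rank permutations for n <= 7 and falls
    back to seeded Monte-Carlo otherwise; ``t_approx`` uses the
    t-distributed statistic with n - 2 degrees of freedom.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 4:
        raise InvalidInputError("series must have equal length >= 4")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise InvalidInputError("constant series: correlation undefined")
    rx, ry = rankdata(xa), rankdata(ya)
    rho = _pearson(rx, ry)
    n = xa.size
    if method == "t_approx":
        if abs(rho) >= 1.0:
            p = 0.0 if rho > 0 else 1.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(stats.t.sf(t, df=n - 2))
        return rho, p
    if method != "exact":
        raise InvalidInputError(f"unknown method {method!r}")
    if n <= 7:
        hits = total = 0
        for perm in permutations(range(n)):
            r = _pearson(rx, ry[list(perm)])
            total += 1
            if r >= rho - 1e-12:
                hits += 1
        return rho, hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r = _pearson(rx, ry[rng.permutation(n)])
        if r >= rho - 1e-12:
            hits += 1
    return rho, (1 + hits) / (1 + n_perm)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / math.sqrt((a @ a) * (b @ b)))


def build_network(
    table: AsvTable,
    classes: pd.DataFrame,
    methanogens: set[str],
    alpha: float = 0.05,
    top_n: int = 1000,
    method: str = "mc",
    n_perm: int = 999,
    seed: int = 0,
    condition: str = "",
) -> nx.Graph:
    """Typed co-occurrence network for one condition.

    All pairwise Spearman correlations among the ``top_n`` most abundant
    taxa are tested one-sided for positive association (``mc``: seeded
    permutation null sharing one permutation per iteration across pairs;
    ``t_approx``: t-distribution).  BH adjustment runs over all tested
    pairs within this network; edges require rho > 0 and q < alpha.
    Every retained taxon is a node; constant taxa contribute no edges
    (logged).  Node attributes: nh3_class, is_methanogen, node_type.
    """
    if len(table.samples) < 4:
        raise InsufficientSamplesError(
            f"need >= 4 samples for network construction, got {len(table.samples)}"
        )
    sub = top_n_taxa(table, top_n)
    missing = [t for t in sub.taxa if t not in classes.index]
    if missing:
        raise InvalidInputError(f"no niche class for taxa {missing[:5]}...")
    mat = sub.data.to_numpy(dtype=float)
    taxa = sub.taxa
    m, n = mat.shape
    ranks = np.apply_along_axis(rankdata, 1, mat)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.info("build_network: %d constant taxa excluded from edges", constant.sum())
    z = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((z * z).sum(axis=1))
    norm[constant] = 1.0
    z = z / norm[:, None]
    rho = z @ z.T

    iu = np.triu_indices(m, k=1)
    ok = ~(constant[iu[0]] | constant[iu[1]])
    rho_obs = rho[iu]
    if method == "mc":
        rng = np.random.default_rng(seed)
        exceed = np.zeros(iu[0].size, dtype=np.int64)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            null = z @ z[:, perm].T
            exceed += null[iu] >= rho_obs - 1e-12
        p = (1 + exceed) / (1 + n_perm)
    elif method == "t_approx":
        r = np.clip(rho_obs, -0.999999999, 0.999999999)
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = stats.t.sf(t, df=n - 2)
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    q = np.full(p.shape, np.nan)
    q[ok] = bh_adjust(p[ok])

    g = nx.Graph(condition=condition, alpha=alpha)
    for t in taxa:
        cls = str(classes.loc[t, "nh3_class"])
        is_m = t in methanogens
        base = "sensitive" if cls == "sensitive" else "tolerant"
        g.add_node(
            t,
            nh3_class=cls,
            is_methanogen=is_m,
            node_type=f"{base}_methanogen" if is_m else base,
        )
    for idx in range(iu[0].size):
        if not ok[idx]:
            continue
        if rho_obs[idx] > 0 and q[idx] < alpha:
            g.add_edge(
                taxa[iu[0][idx]],
                taxa[iu[1][idx]],
                rho=float(rho_obs[idx]),
                p=float(p[idx]),
                q=float(q[idx]),
            )
    return g


def components(net: nx.Graph) -> tuple[dict[str, int], pd.DataFrame]:
    """Connected-component cluster ids and a per-cluster summary.

    Components are ordered by size (ties: smallest member id) so ids are
    deterministic.  The summary counts node types per cluster and flags
    methanogen presence.
    """
    comps = sorted(
        (sorted(c) for c in nx.connected_components(net)),
        key=lambda c: (-len(c), c[0]),
    )
    assignment = {node: i for i, comp in enumerate(comps) for node in comp}
    rows = []
    for i, comp in enumerate(comps):
        counts = {t: 0 for t in NODE_TYPES}
        for node in comp:
            counts[net.nodes[node]["node_type"]] += 1
        rows.append(
            {
                "cluster": i,
                "size": len(comp),
                **counts,
                "has_methanogen": any(net.nodes[n]["is_methanogen"] for n in comp),
            }
        )
    return assignment, pd.DataFrame(rows)


@dataclass(frozen=True)
class CompositionTest:
    """Chi-square comparison of node-type composition across networks."""

    table: pd.DataFrame  # networks x node types
    chi2: float
    df: int
    p_value: float


def node_type_counts(nets: list[nx.Graph]) -> pd.DataFrame:
    rows = {}
    for i, g in enumerate(nets):
        label = g.graph.get("condition") or f"network_{i}"
        counts = {t: 0 for t in NODE_TYPES}
        for _, attrs in g.nodes(data=True):
            counts[attrs["node_type"]] += 1
        rows[label] = counts
    return pd.DataFrame.from_dict(rows, orient="index")


def composition_chisq(networks: list[nx.Graph]) -> CompositionTest:
    """Pearson chi-square on the networks x node-type count table.

    All-zero rows/columns are degenerate; zero-count node types that are
    absent from *every* network are dropped from the table first.
    """
    if len(networks) < 2:
        raise InvalidInputError("need at least 2 networks")
    table = node_type_counts(networks)
    table = table.loc[:, table.sum(axis=0) > 0]
    if (table.sum(axis=1) == 0).any() or table.shape[1] < 2:
        raise DegenerateTableError("contingency table has an all-zero row or column")
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return CompositionTest(table=table, chi2=float(chi2), df=int(df), p_value=float(p))
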
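"""Hurlbert niche breadth along the free-ammonia gradient.

Each sample is treated as a resource state whose availability r_j is
proportional to its measured NH3 concentration.  For a taxon with relative
abundance profile p_j over samples,

    B  = 1 / sum_j(p_j^2 / r_j)          (Hurlbert's niche breadth)
    B' = (B - r_min) / (1 - r_min)       (standardised to [0, 1])

A taxon whose abundance concentrates in low-NH3 samples has B' near 0
(ammonia sensitive); one concentrated where NH3 is high approaches 1
(enriched).  Significance is judged against a null distribution of B'
values from randomly generated taxa (observed profiles permuted across
samples), with Benjamini-Hochberg control of the false discovery rate.
The study-constant thresholds 0.24 (sensitive) and 0.88 (enriched) can be
applied directly instead of data-derived null quantiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .abundance import AsvTable
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

#: Fixed classification thresholds reported for ammonia niche breadth.
PAPER_THRESHOLDS = (0.24, 0.88)


@dataclass(frozen=True)
class NullModel:
    """Empirical null distribution of standardised niche breadth."""

    n_null: int
    null_b: np.ndarray
    lower_threshold: float
    upper_threshold: float
    alpha: float
    seed: int


def hurlbert_bn(profile, nh3) -> tuple[float, float]:
    """Raw and standardised Hurlbert niche breadth of one taxon.

    Parameters
    ----------
    profile : array-like
        Non-negative abundances per sample (normalised internally).
    nh3 : array-like
        Positive per-sample NH3 concentrations defining resource
        availability r_j = nh3_j / sum(nh3).

    Returns
    -------
    (b_raw, b_std)
        ``b_raw`` in [r_min, 1]; ``b_std`` in [0, 1].
    """
    p = np.asarray(profile, dtype=float)
    r_raw = np.asarray(nh3, dtype=float)
    if p.shape != r_raw.shape:
        raise InvalidInputError("profile and nh3 must have equal length")
    if p.size < 3:
        raise InvalidInputError("need at least 3 samples")
    if (p < 0).any():
        raise InvalidInputError("profile must be non-negative")
    if (r_raw <= 0).any():
        raise InvalidInputError("all nh3 values must be > 0")
    total = p.sum()
    if total == 0:
        raise InvalidInputError("zero-sum profile")
    p = p / total
    r = r_raw / r_raw.sum()
    b = 1.0 / float(np.sum(np.where(p > 0, p * p / r, 0.0)))
    r_min = float(r.min())
    b_std = (b - r_min) / (1.0 - r_min)
    return b, b_std


def _bstd_matrix(profiles: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Vectorised B' for a stack of normalised profiles (rows)."""
    denom = (profiles * profiles / r).sum(axis=1)
    b = 1.0 / denom
    r_min = r.min()
    return (b - r_min) / (1.0 - r_min)


def null_model(
    table: AsvTable,
    nh3,
    n_null: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    kind: str = "random",
    concentration: float = 2.0,
) -> NullModel:
    """Null distribution of B' from randomly generated taxa.

    ``kind="random"`` (default): each null taxon is a uniform-random
    proportion vector over the resource states (flat Dirichlet), i.e. a
    taxon with no structured NH3 response; observed taxa whose profiles
    are more extreme than such random taxa in either direction are
    classifiable.  ``kind="permutation"``: each null taxon is a randomly
    chosen observed profile permuted across states (preserves the
    abundance distribution, destroys the NH3 association; note its tails
    track the most concentrated observed taxa, making it conservative
    when strong responders are present).  Classification thresholds are
    the ``alpha`` and ``1 - alpha`` empirical quantiles of the null B'.
    """
    if n_null < 99:
        raise InvalidInputError(f"n_null must be >= 99, got {n_null}")
    if not 0 < alpha < 0.5:
        raise InvalidInputError(f"alpha must be in (0, 0.5), got {alpha}")
    mat = table.data.to_numpy(dtype=float)
    mat = mat[mat.sum(axis=1) > 0]
    if mat.shape[0] < 2:
        raise InvalidInputError("need at least 2 observed taxa with non-zero totals")
    r_raw = np.asarray(nh3, dtype=float)
    if r_raw.size != mat.shape[1]:
        raise InvalidInputError("nh3 length must match number of samples")
    if (r_raw <= 0).any():
        raise InvalidInputError("all nh3 values must be > 0")
    r = r_raw / r_raw.sum()
    rng = np.random.default_rng(seed)
    if kind == "random":
        if concentration <= 0:
            raise InvalidInputError("concentration must be > 0")
        nulls = rng.dirichlet(np.full(mat.shape[1], concentration), size=n_null)
    elif kind == "permutation":
        picks = rng.integers(0, mat.shape[0], size=n_null)
        nulls = np.empty((n_null, mat.shape[1]))
        for i, k in enumerate(picks):
            nulls[i] = rng.permutation(mat[k])
        nulls = nulls / nulls.sum(axis=1, keepdims=True)
    else:
        raise InvalidInputError(f"unknown null kind {kind!r}")
    null_b = _bstd_matrix(nulls, r)
    lower, upper = np.quantile(null_b, [alpha, 1.0 - alpha])
    return NullModel(
        n_null=n_null,
        null_b=null_b,
        lower_threshold=float(lower),
        upper_threshold=float(upper),
        alpha=alpha,
        seed=seed,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_taxa(
    b_std: pd.Series,
    null: NullModel | None = None,
    alpha: float = 0.05,
    fixed_thresholds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Label taxa sensitive / tolerant / enriched from their B' values.

    With a null model, a taxon is *sensitive* when B' falls below the
    lower null quantile with BH-adjusted q < alpha, *enriched* when above
    the upper quantile with q < alpha, otherwise *tolerant*.  With
    ``fixed_thresholds`` (e.g. :data:`PAPER_THRESHOLDS`) the two cut-offs
    are applied directly.
    """
    if b_std.isna().any():
        raise InvalidInputError("missing B' value")
    if null is None and fixed_thresholds is None:
        raise InvalidInputError("provide a null model or fixed thresholds")
    out = pd.DataFrame({"b_std": b_std})
    out.index.name = "taxon_id"
    if null is not None:
        nb = np.sort(null.null_b)
        b = b_std.to_numpy()
        n = nb.size
        le = np.searchsorted(nb, b, side="right")  # #{null <= b}
        ge = n - np.searchsorted(nb, b, side="left")  # #{null >= b}
        p_low = (1 + le) / (n + 1)
        p_high = (1 + ge) / (n + 1)
        p = np.minimum(1.0, 2.0 * np.minimum(p_low, p_high))
        out["p_value"] = p
        out["q_value"] = bh_adjust(p)
    else:
        out["p_value"] = np.nan
        out["q_value"] = np.nan
    if fixed_thresholds is not None:
        lower, upper = fixed_thresholds
        cls = np.where(
            out["b_std"] < lower,
            "sensitive",
            np.where(out["b_std"] > upper, "enriched", "tolerant"),
        )
    else:
        lower, upper = null.lower_threshold, null.upper_threshold
        sig = out["q_value"] < alpha
        cls = np.where(
            (out["b_std"] < lower) & sig,
            "sensitive",
            np.where((out["b_std"] > upper) & sig, "enriched", "tolerant"),
        )
    out["nh3_class"] = cls
    return out


def aggregate_resource_states(
    table: AsvTable, nh3, groups
) -> tuple[AsvTable, np.ndarray]:
    """Average abundances and NH3 into labelled resource states.

    ``groups`` maps each sample (by position or id) to a resource-state
    label (e.g. medium x day).  Replicate averaging stabilises the
    per-state abundance profile; the state's availability is its mean
    NH3.  States are ordered by first appearance.
    """
    labels = list(groups)
    if len(labels) != len(table.samples):
        raise InvalidInputError("groups must label every sample")
    r_raw = np.asarray(nh3, dtype=float)
    order: list = []
    for lab in labels:
        if lab not in order:
            order.append(lab)
    if len(order) < 3:
        raise InvalidInputError("need at least 3 resource states")
    cols = {}
    nh3_states = []
    arr = table.data.to_numpy(dtype=float)
    for lab in order:
        idx = [i for i, g in enumerate(labels) if g == lab]
        cols[str(lab)] = arr[:, idx].mean(axis=1)
        nh3_states.append(r_raw[idx].mean())
    agg = AsvTable(pd.DataFrame(cols, index=table.taxa), mode=table.mode)
    return agg, np.asarray(nh3_states)


def niche_classification(
    table: AsvTable,
    nh3,
    n_null: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    fixed_thresholds: tuple[float, float] | None = None,
    min_samples: int = 3,
    resource_groups=None,
    null_kind: str = "random",
    concentration: float = 2.0,
) -> tuple[pd.DataFrame, NullModel]:
    """Full per-taxon niche-breadth classification for one community.

    Taxa observed in fewer than ``min_samples`` samples are excluded
    (their B' is unstable) with a logged message.  When
    ``resource_groups`` is given, samples are first averaged into those
    resource states (replicates of one experimental NH3 condition);
    otherwise every sample is its own state.  Returns a DataFrame with
    columns b_raw, b_std, p_value, q_value, nh3_class, and the null
    model used.
    """
    mat_full = table.data.to_numpy(dtype=float)
    occupancy = (mat_full > 0).sum(axis=1)
    keep = (occupancy >= min_samples) & (mat_full.sum(axis=1) > 0)
    dropped = [t for t, k in zip(table.taxa, keep) if not k]
    if dropped:
        logger.info(
            "niche: excluding %d taxa observed in < %d samples", len(dropped), min_samples
        )
    if resource_groups is not None:
        table, nh3 = aggregate_resource_states(table, nh3, resource_groups)
    r_raw = np.asarray(nh3, dtype=float)
    mat = table.data.to_numpy(dtype=float)
    null = null_model(
        table,
        r_raw,
        n_null=n_null,
        alpha=alpha,
        seed=seed,
        kind=null_kind,
        concentration=concentration,
    )
    records = {}
    for taxon, row, k in zip(table.taxa, mat, keep):
        if not k:
            continue
        b, b_std = hurlbert_bn(row, r_raw)
        records[taxon] = {"b_raw": b, "b_std": b_std}
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "taxon_id"
    classified = classify_taxa(
        df["b_std"], null=null, alpha=alpha, fixed_thresholds=fixed_thresholds
    )
    df["p_value"] = classified["p_value"]
    df["q_value"] = classified["q_value"]
    df["nh3_class"] = classified["nh3_class"]
    return df, null
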
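"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (exhaustive enumeration, direct
formula transcription, Monte-Carlo) and independent of the package's
optimised code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

IDX = {c: i for i, c in enumerate("ACGT")}


def brute_force_forward_bits(hmm, seq: str) -> float:
    """Sum P(path, seq)/P(seq | background) over *all* state paths.

    Recursive enumeration over the match/insert/delete topology with
    local entry/exit and geometric flanks; feasible only for tiny models
    and sequences.
    """
    L = hmm.n_match
    x = [IDX[c] for c in seq.upper()]
    n = len(x)
    eps, eta = hmm.epsilon, hmm.eta
    bg = 0.25
    total = 0.0

    def emit(k, i):
        return hmm.match_emissions[k][x[i]] / bg

    def core(state, k, i, prob):
        nonlocal total
        if state == "M":
            p_exit = eps if k < L - 1 else 1.0
            total += prob * p_exit * (eta ** (n - i)) * (1 - eta)
            if k < L - 1:
                if i < n:
                    core("M", k + 1, i + 1, prob * hmm.t_mm[k] * emit(k + 1, i))
                    core("I", k, i + 1, prob * hmm.t_mi[k])
                core("D", k + 1, i, prob * hmm.t_md[k])
        elif state == "I":
            if i < n:
                core("I", k, i + 1, prob * hmm.t_ii[k])
                core("M", k + 1, i + 1, prob * hmm.t_im[k] * emit(k + 1, i))
        else:  # delete
            if k == L - 1:
                total += prob * (eta ** (n - i)) * (1 - eta)
            else:
                if i < n:
                    core("M", k + 1, i + 1, prob * hmm.t_dm[k] * emit(k + 1, i))
                core("D", k + 1, i, prob * hmm.t_dd[k])

    for flank in range(n):
        p_flank = (eta**flank) * (1 - eta)
        for k0 in range(L):
            core("M", k0, flank + 1, p_flank * hmm.entry[k0] * emit(k0, flank))
    return math.log2(total)


def hurlbert_by_hand(p, r):
    """Direct transcription: B = 1/sum(p^2/r), B' = (B - rmin)/(1 - rmin)."""
    p = np.asarray(p, float)
    r = np.asarray(r, float)
    p = p / p.sum()
    r = r / r.sum()
    b = 1.0 / sum(pi * pi / ri for pi, ri in zip(p, r) if pi > 0)
    return b, (b - r.min()) / (1.0 - r.min())


def bh_step_up(p):
    """Benjamini-Hochberg by the literal step-up formula."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def spearman_rho(x, y):
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def exact_spearman_p_positive(x, y):
    """One-sided positive p by full enumeration of rank permutations."""
    y = np.asarray(y, float)
    obs = spearman_rho(x, y)
    hits = total = 0
    for perm in itertools.permutations(range(len(y))):
        total += 1
        if spearman_rho(x, y[list(perm)]) >= obs - 1e-12:
            hits += 1
    return hits / total


def chi2_mc_p(table, n_draws=100_000, seed=0):
    """Monte-Carlo chi-square p under the independence multinomial."""
    obs = np.asarray(table, float)
    n = obs.sum()
    probs = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / (n * n)
    expected = probs * n
    chi2_obs = ((obs - expected) ** 2 / expected).sum()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(int(n), probs.ravel(), size=n_draws).reshape(
        n_draws, *obs.shape
    )
    # each resampled table is tested against its own margin expectation
    row = draws.sum(axis=2, keepdims=True)
    col = draws.sum(axis=1, keepdims=True)
    exp_k = row * col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp_k > 0, (draws - exp_k) ** 2 / exp_k, 0.0)
    chi2_null = terms.sum(axis=(1, 2))
    return float((chi2_null >= chi2_obs - 1e-9).mean())


def anosim_exhaustive_p(dist, groups):
    """Exhaustive label-permutation p for the ANOSIM R statistic."""
    from scipy.stats import rankdata

    d = np.asarray(dist, float)
    labels = np.asarray(groups)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])

    def r_stat(lab):
        within = lab[iu[0]] == lab[iu[1]]
        rw = ranks[within].mean()
        rb = ranks[~within].mean()
        return (rb - rw) / (ranks.size / 2.0)

    obs = r_stat(labels)
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        lab = labels[list(perm)]
        total += 1
        if r_stat(lab) >= obs - 1e-12:
            hits += 1
    return obs, hits / total
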
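"""Profile hidden Markov model for marker-gene screening.

A profile HMM is estimated from a gapped reference multiple alignment of
methanogen 16S rRNA genes: alignment columns with fewer than 50% gaps
become match states (position-specific emission distributions over
A/C/G/T); insert states emit the background distribution; delete states
allow skipping match positions.  Scoring is *local*: the model may be
entered at any match state and left from any match state, with geometric
flanking states absorbing unmodelled sequence — appropriate because query
amplicons cover only a sub-region (e.g. V4) of full-length references.

Scores are log-odds in bits: log2 P(seq | profile) / P(seq | background),
with P(seq | profile) computed by the forward algorithm over all paths.
The Viterbi path provides a deterministic alignment of a query to the
match states, used downstream for identity distances.

Architecture (0-indexed, L match states):

    S -> N(loop eta) -> B -> M_k (uniform entry 1/L)
    M_k -> {M_{k+1}, I_k, D_{k+1}} * (1-eps)  and  M_k -> E (eps)
    I_k -> {M_{k+1}, I_k};  D_k -> {M_{k+1}, D_{k+1}};  M_{L-1}, D_{L-1} -> E
    E -> C(loop eta) -> T
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import FormatError, InvalidInputError

ALPHABET = "ACGT"
_IDX = {c: i for i, c in enumerate(ALPHABET)}
_NEG = -np.inf


@dataclass
class ProfileHmm:
    """Match/insert/delete profile model with local entry/exit.

    Transition arrays are indexed by the *source* match/insert/delete
    position; ``t_dm[k]`` is D_k -> M_{k+1} (meaningful for 1 <= k <= L-2).
    All stored probabilities are linear; scoring converts to log space.
    """

    n_match: int
    match_emissions: np.ndarray  # (L, 4)
    insert_emissions: np.ndarray  # (4,)
    background: np.ndarray  # (4,)
    t_mm: np.ndarray  # (L-1,) M_k -> M_{k+1}
    t_mi: np.ndarray  # (L-1,) M_k -> I_k
    t_md: np.ndarray  # (L-1,) M_k -> D_{k+1}
    t_im: np.ndarray  # (L-1,) I_k -> M_{k+1}
    t_ii: np.ndarray  # (L-1,) I_k -> I_k
    t_dm: np.ndarray  # (L,)   D_k -> M_{k+1}
    t_dd: np.ndarray  # (L,)   D_k -> D_{k+1}
    entry: np.ndarray  # (L,)   B -> M_k
    epsilon: float = 0.01  # M_k -> E early-exit mass (k < L-1)
    eta: float = 0.9  # flank self-loop probability
    match_columns: list = field(default_factory=list)

    def __post_init__(self) -> None:
        L = self.n_match
        if L < 1:
            raise InvalidInputError("profile needs at least one match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidInputError("match emissions must sum to 1")
        for name in ("insert_emissions", "background", "entry"):
            if not np.isclose(getattr(self, name).sum(), 1.0, atol=1e-9):
                raise InvalidInputError(f"{name} must sum to 1")
        if L > 1:
            total = self.t_mm + self.t_mi + self.t_md
            if not np.allclose(total, 1.0 - self.epsilon, atol=1e-9):
                raise InvalidInputError("match transitions must sum to 1 - epsilon")
            if not np.allclose(self.t_im + self.t_ii, 1.0, atol=1e-9):
                raise InvalidInputError("insert transitions must sum to 1")
            inner = slice(1, L - 1)
            if L > 2 and not np.allclose(
                self.t_dm[inner] + self.t_dd[inner], 1.0, atol=1e-9
            ):
                raise InvalidInputError("delete transitions must sum to 1")


def _validate_msa(msa: Mapping[str, str] | Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    pairs = list(msa.items()) if isinstance(msa, Mapping) else [tuple(p) for p in msa]
    if not pairs:
        raise FormatError("alignment has no sequences")
    width = len(pairs[0][1])
    for name, seq in pairs:
        if len(seq) != width:
            raise FormatError(f"ragged alignment: sequence {name!r} has length {len(seq)}")
        bad = set(seq.upper()) - set(ALPHABET + "-")
        if bad:
            raise FormatError(f"illegal symbol(s) {sorted(bad)} in sequence {name!r}")
    return [(name, seq.upper()) for name, seq in pairs]


def build_profile_hmm(
    msa: Mapping[str, str] | Sequence[tuple[str, str]],
    pseudocount: float = 1.0,
    epsilon: float = 0.01,
    eta: float = 0.9,
) -> ProfileHmm:
    """Estimate a profile HMM from a gapped reference alignment.

    Columns with < 50% gaps become match states.  Emission and transition
    probabilities are maximum-likelihood estimates with Laplace
    ``pseudocount`` smoothing; the background is uniform 0.25.
    """
    pairs = _validate_msa(msa)
    n_seq = len(pairs)
    width = len(pairs[0][1])
    cols = np.array([[s[c] for _, s in pairs] for c in range(width)])  # width x n_seq
    gap_frac = (cols == "-").mean(axis=1)
    match_cols = [c for c in range(width) if gap_frac[c] < 0.5]
    L = len(match_cols)
    if L < 1:
        raise InvalidInputError("no column qualifies as a match state")

    emissions = np.full((L, 4), pseudocount, dtype=float)
    for k, c in enumerate(match_cols):
        for ch in cols[c]:
            if ch != "-":
                emissions[k, _IDX[ch]] += 1.0
    emissions /= emissions.sum(axis=1, keepdims=True)

    # per-position transition counts along each sequence's local path
    c_mm = np.zeros(max(L - 1, 1))
    c_mi = np.zeros(max(L - 1, 1))
    c_md = np.zeros(max(L - 1, 1))
    c_im = np.zeros(max(L - 1, 1))
    c_ii = np.zeros(max(L - 1, 1))
    c_dm = np.zeros(L)
    c_dd = np.zeros(L)
    match_set = {c: k for k, c in enumerate(match_cols)}
    for _, seq in pairs:
        events: list[tuple[str, int]] = []
        for c in range(width):
            if c in match_set:
                k = match_set[c]
                events.append(("M" if seq[c] != "-" else "D", k))
            elif seq[c] != "-":
                k_before = sum(1 for mc in match_cols if mc < c)
                if 1 <= k_before <= L - 1:
                    events.append(("I", k_before - 1))
        # trim to the local span between first and last emitting match
        m_pos = [i for i, (s, _) in enumerate(events) if s == "M"]
        if not m_pos:
            continue
        span = events[m_pos[0] : m_pos[-1] + 1]
        for (s1, k1), (s2, _k2) in zip(span, span[1:]):
            if s1 == "M" and s2 == "M":
                c_mm[k1] += 1
            elif s1 == "M" and s2 == "I":
                c_mi[k1] += 1
            elif s1 == "M" and s2 == "D":
                c_md[k1] += 1
            elif s1 == "I" and s2 == "M":
                c_im[k1] += 1
            elif s1 == "I" and s2 == "I":
                c_ii[k1] += 1
            elif s1 == "D" and s2 == "M":
                c_dm[k1] += 1
            elif s1 == "D" and s2 == "D":
                c_dd[k1] += 1

    pc = pseudocount
    if L > 1:
        m_tot = c_mm + c_mi + c_md + 3 * pc
        t_mm = (c_mm + pc) / m_tot * (1.0 - epsilon)
        t_mi = (c_mi + pc) / m_tot * (1.0 - epsilon)
        t_md = (c_md + pc) / m_tot * (1.0 - epsilon)
        i_tot = c_im + c_ii + 2 * pc
        t_im = (c_im + pc) / i_tot
        t_ii = (c_ii + pc) / i_tot
        t_dm = np.zeros(L)
        t_dd = np.zeros(L)
        d_tot = c_dm + c_dd + 2 * pc
        t_dm[1 : L - 1] = ((c_dm + pc) / d_tot)[1 : L - 1]
        t_dd[1 : L - 1] = ((c_dd + pc) / d_tot)[1 : L - 1]
    else:
        t_mm = t_mi = t_md = t_im = t_ii = np.zeros(0)
        t_dm = t_dd = np.zeros(1)

    return ProfileHmm(
        n_match=L,
        match_emissions=emissions,
        insert_emissions=np.full(4, 0.25),
        background=np.full(4, 0.25),
        t_mm=t_mm,
        t_mi=t_mi,
        t_md=t_md,
        t_im=t_im,
        t_ii=t_ii,
        t_dm=t_dm,
        t_dd=t_dd,
        entry=np.full(L, 1.0 / L),
        epsilon=epsilon,
        eta=eta,
        match_columns=match_cols,
    )


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    if not seq:
        raise InvalidInputError("empty sequence")
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise InvalidInputError(f"non-ACGT symbol(s) {sorted(bad)}")
    return np.array([_IDX[c] for c in seq], dtype=np.int64)


def _log(x: np.ndarray | float) -> np.ndarray | float:
    with np.errstate(divide="ignore"):
        return np.log(x)


def _exit_logs(hmm: ProfileHmm) -> np.ndarray:
    """log P(M_k -> E): epsilon for inner states, 1 for the last."""
    L = hmm.n_match
    out = np.full(L, _log(hmm.epsilon))
    out[L - 1] = 0.0
    return out


def score_sequence(hmm: ProfileHmm, seq: str) -> float:
    """Forward log-odds score of ``seq`` in bits.

    Sums over all state paths; insert and flank emissions equal the
    background, so their emission terms cancel in the odds ratio.
    """
    x = _encode(seq)
    L, n = hmm.n_match, x.size
    le = _log(hmm.match_emissions) - _log(hmm.background)  # (L, 4) odds
    l_entry = _log(hmm.entry)
    l_eta, l_end = _log(hmm.eta), _log(1.0 - hmm.eta)
    l_mm, l_mi, l_md = _log(hmm.t_mm), _log(hmm.t_mi), _log(hmm.t_md)
    l_im, l_ii = _log(hmm.t_im), _log(hmm.t_ii)
    l_dm, l_dd = _log(hmm.t_dm), _log(hmm.t_dd)
    l_me = _exit_logs(hmm)

    M = np.full(L, _NEG)
    I = np.full(max(L - 1, 0), _NEG)
    D = np.full(L, _NEG)
    N = 0.0
    B = l_end  # N -> B without emission
    C = _NEG
    # delete-chain helper: prefix sums of l_dd for the accumulate trick
    if L > 1:
        P = np.concatenate(([0.0], np.cumsum(l_dd[1 : L - 1])))  # len L-1, for D_1..D_{L-1}
    for i in range(n):
        e = le[:, x[i]]
        cand = np.full((4, L), _NEG)
        cand[0] = B + l_entry
        if L > 1:
            cand[1, 1:] = M[:-1] + l_mm
            cand[2, 1:] = I + l_im
            cand[3, 1:] = D[:-1] + l_dm[: L - 1]
        newM = e + _logsum_rows(cand)
        # deletes at this position: D_k from newM[k-1] (M->D) or chain D_{k-1}
        newD = np.full(L, _NEG)
        if L > 1:
            A = newM[: L - 1] + l_md  # candidate M_{k} -> D_{k+1}, k=0..L-2
            newD[1:] = P + np.logaddexp.accumulate(A - P)
        newI = np.full(max(L - 1, 0), _NEG)
        if L > 1:
            newI = np.logaddexp(M[: L - 1] + l_mi, I + l_ii)
        E = _logsumexp(np.concatenate((newM + l_me, [newD[L - 1] if L > 1 else _NEG])))
        C = np.logaddexp(C + l_eta, E)
        N = N + l_eta
        B = N + l_end
        M, I, D = newM, newI, newD
    score_nats = C + l_end
    return float(score_nats / np.log(2.0))


def _logsum_rows(arr: np.ndarray) -> np.ndarray:
    """Column-wise logsumexp of a small 2-D array, -inf safe."""
    mx = arr.max(axis=0)
    out = np.full(arr.shape[1], _NEG)
    ok = np.isfinite(mx)
    if ok.any():
        out[ok] = mx[ok] + np.log(np.exp(arr[:, ok] - mx[ok]).sum(axis=0))
    return out


def _logsumexp(v: np.ndarray) -> float:
    mx = v.max()
    if not np.isfinite(mx):
        return _NEG
    return float(mx + np.log(np.exp(v - mx).sum()))


def viterbi_match_alignment(hmm: ProfileHmm, seq: str) -> str:
    """Align ``seq`` to the match states along the Viterbi path.

    Returns a string of length ``n_match``: the residue emitted at each
    match state, or ``-`` where the state was deleted or outside the
    local alignment span.
    """
    x = _encode(seq)
    L, n = hmm.n_match, x.size
    le = _log(hmm.match_emissions) - _log(hmm.background)
    l_entry = _log(hmm.entry)
    l_eta, l_end = _log(hmm.eta), _log(1.0 - hmm.eta)
    l_mm, l_mi, l_md = _log(hmm.t_mm), _log(hmm.t_mi), _log(hmm.t_md)
    l_im, l_ii = _log(hmm.t_im), _log(hmm.t_ii)
    l_dm, l_dd = _log(hmm.t_dm), _log(hmm.t_dd)
    l_me = _exit_logs(hmm)

    Ms = np.full((n + 1, L), _NEG)
    Is = np.full((n + 1, max(L - 1, 0)), _NEG)
    Ds = np.full((n + 1, L), _NEG)
    ptrM = np.zeros((n + 1, L), dtype=np.int8)  # 0=B 1=M 2=I 3=D
    ptrI = np.zeros((n + 1, max(L - 1, 0)), dtype=np.int8)  # 0=M 1=I
    Ns = l_eta * np.arange(n + 1)
    Bs = Ns + l_end
    if L > 1:
        P = np.concatenate(([0.0], np.cumsum(l_dd[1 : L - 1])))
    for i in range(1, n + 1):
        e = le[:, x[i - 1]]
        cand = np.full((4, L), _NEG)
        cand[0] = Bs[i - 1] + l_entry
        if L > 1:
            cand[1, 1:] = Ms[i - 1, :-1] + l_mm
            cand[2, 1:] = Is[i - 1] + l_im
            cand[3, 1:] = Ds[i - 1, :-1] + l_dm[: L - 1]
        ptrM[i] = cand.argmax(axis=0)
        Ms[i] = e + cand.max(axis=0)
        if L > 1:
            A = Ms[i, : L - 1] + l_md
            Ds[i, 1:] = P + np.maximum.accumulate(A - P)
            ic = np.stack((Ms[i - 1, : L - 1] + l_mi, Is[i - 1] + l_ii))
            ptrI[i] = ic.argmax(axis=0)
            Is[i] = ic.max(axis=0)
    # best exit over (i, k): core ends at residue i, remaining n-i residues in C
    best, bi, bk, b_from_d = _NEG, -1, -1, False
    for i in range(1, n + 1):
        tail = (n - i) * l_eta
        ends = Ms[i] + l_me + tail
        k = int(ends.argmax())
        if ends[k] > best:
            best, bi, bk, b_from_d = float(ends[k]), i, k, False
        if L > 1 and Ds[i, L - 1] + tail > best:
            best, bi, bk, b_from_d = float(Ds[i, L - 1] + tail), i, L - 1, True
    if not np.isfinite(best):
        raise InvalidInputError("no finite alignment path")
    out = ["-"] * L
    i, k, state = bi, bk, "D" if b_from_d else "M"
    while True:
        if state == "M":
            out[k] = ALPHABET[x[i - 1]]
            move = ptrM[i, k]
            if move == 0:
                break
            state = {1: "M", 2: "I", 3: "D"}[int(move)]
            i, k = i - 1, k - 1
        elif state == "D":
            # same-position delete chain: from M_{k-1} or D_{k-1}
            if np.isclose(Ds[i, k], Ms[i, k - 1] + l_md[k - 1]):
                state, k = "M", k - 1
            else:
                k = k - 1
        else:  # insert I_k
            move = ptrI[i, k]
            i = i - 1
            if move == 0:
                state = "M"
            # else stay in insert at same k
    return "".join(out)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erickson).

    Builds the transition multigraph of the sequence and samples a random
    Eulerian path with the original start and end symbols.
    """
    seq = seq.upper()
    if len(seq) < 3 or len(set(seq)) < 2:
        return seq
    succ: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        succ.setdefault(a, []).append(b)
    last_char = seq[-1]
    vertices = sorted(succ.keys() | {last_char})
    for _ in range(1000):
        last_edge = {}
        ok = True
        for v in vertices:
            if v == last_char or v not in succ:
                continue
            last_edge[v] = succ[v][rng.integers(len(succ[v]))]
        # every vertex with out-edges must reach last_char via last edges
        for v in last_edge:
            cur, steps = v, 0
            while cur != last_char and steps <= len(vertices):
                if cur not in last_edge:
                    ok = False
                    break
                cur = last_edge[cur]
                steps += 1
            if not ok or cur != last_char:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - bounded retry safeguard
        return seq
    ordered: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(succ.get(v, []))
        if v in last_edge:
            edges.remove(last_edge[v])
        perm = rng.permutation(len(edges))
        edges = [edges[j] for j in perm]
        if v in last_edge:
            edges.append(last_edge[v])
        ordered[v] = edges
    out = [seq[0]]
    ptr = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = ordered[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)
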
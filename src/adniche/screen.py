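"""Methanogen screening of ASV sequences with a reference profile HMM.

The profile HMM built from the reference methanogen alignment is scored
against every query ASV.  Significance is calibrated from a null score
distribution of dinucleotide-shuffled input sequences (shuffling
preserves composition and dinucleotide bias but destroys positional
signal); a query is called a putative methanogen when its bit score
exceeds a high percentile (default 0.99) of that null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import InvalidInputError
from .hmm import ProfileHmm, dinucleotide_shuffle, score_sequence, viterbi_match_alignment


def read_fasta(path) -> dict[str, str]:
    """Read sequences keyed by record id (Biopython FASTA parser)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


@dataclass
class ScreenResult:
    """Per-ASV bit scores, the null threshold and the called set."""

    scores: pd.DataFrame  # asv_id index; bit_score, called
    threshold: float
    null_scores: np.ndarray
    quantile: float

    @property
    def called(self) -> list[str]:
        return list(self.scores.index[self.scores["called"]])

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out["threshold"] = self.threshold
        out.to_csv(path, sep="\t", index_label="asv_id")


def screen_methanogens(
    hmm: ProfileHmm,
    asvs: dict[str, str],
    n_null: int = 200,
    quantile: float = 0.99,
    seed: int = 0,
) -> ScreenResult:
    """Call putative methanogens among ``asvs`` by HMM bit score.

    The null distribution holds ``n_null`` forward scores of
    dinucleotide-shuffled sequences drawn (with replacement) from the
    input set; the call threshold is its ``quantile`` percentile.
    An empty input yields an empty result, not an error.
    """
    if asvs and n_null < 100:
        raise InvalidInputError(f"n_null must be >= 100, got {n_null}")
    if not 0 < quantile < 1:
        raise InvalidInputError(f"quantile must be in (0, 1), got {quantile}")
    ids = list(asvs)
    if not ids:
        return ScreenResult(
            scores=pd.DataFrame(columns=["bit_score", "called"]),
            threshold=float("nan"),
            null_scores=np.array([]),
            quantile=quantile,
        )
    rng = np.random.default_rng(seed)
    obs = np.array([score_sequence(hmm, asvs[name]) for name in ids])
    picks = rng.integers(0, len(ids), size=n_null)
    null = np.array(
        [score_sequence(hmm, dinucleotide_shuffle(asvs[ids[k]], rng)) for k in picks]
    )
    threshold = float(np.quantile(null, quantile))
    df = pd.DataFrame({"bit_score": obs, "called": obs > threshold}, index=ids)
    df.index.name = "asv_id"
    return ScreenResult(scores=df, threshold=threshold, null_scores=null, quantile=quantile)


def msa_match_strings(msa: dict[str, str], hmm: ProfileHmm) -> dict[str, str]:
    """Project aligned reference sequences onto the HMM match columns."""
    return {
        name: "".join(seq[c] for c in hmm.match_columns) for name, seq in msa.items()
    }


def align_hits_to_matches(
    hmm: ProfileHmm, asvs: dict[str, str], hits: list[str]
) -> dict[str, str]:
    """Viterbi-align called ASVs to the HMM match states."""
    return {name: viterbi_match_alignment(hmm, asvs[name]) for name in hits}
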
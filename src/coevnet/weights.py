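"""Phylogenetic sequence weighting and weighted pair probabilities.

Redundant, near-duplicate sequences in an alignment would otherwise dominate
every pairwise statistic. Each sequence is down-weighted by the size of its
identity neighborhood: w_a = 1 / |{b : seqid(a, b) > t}| with t = 0.80 by
default, the sequence itself included (so 0 < w_a <= 1 and a group of k exact
duplicates contributes total weight 1).

Pair probabilities for two columns are weighted state frequencies over the
sequences that carry a residue (not a gap, not 'X') at *both* columns, with a
single pseudo-count in the denominator: p(s) = count_w(s) / (N_eff + 1) where
N_eff is the sum of weights of the included sequences. These probabilities
are deliberately sub-normalized (they sum to N_eff / (N_eff + 1)); the
covariance metrics consume them as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa_io import AA_INDEX, GAP, GAP_CODE, MSA

DEFAULT_IDENTITY_THRESHOLD = 0.80

#: alphabet tags
BINARY = "2-letter"
FULL = "20-letter"


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical residues over mutually non-gap columns.

    'X' never matches anything, itself included. Returns 0.0 when the two
    sequences share no mutually non-gap column.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    both = 0
    same = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        both += 1
        if x == y and x in AA_INDEX:
            same += 1
    return same / both if both else 0.0


def pairwise_identity_matrix(msa: MSA, chunk: int = 64) -> np.ndarray:
    """N x N matrix of :func:`sequence_identity` values (vectorized)."""
    codes = msa.codes()
    nongap = codes != GAP_CODE
    residue = codes < GAP_CODE  # amino acids only; 'X' can never match
    n = msa.N
    out = np.empty((n, n), dtype=float)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        blk = codes[start:stop]
        both = nongap[start:stop, None, :] & nongap[None, :, :]
        same = (blk[:, None, :] == codes[None, :, :]) & residue[start:stop, None, :] & residue[None, :, :]
        denom = both.sum(axis=2)
        numer = (same & both).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(denom > 0, numer / np.maximum(denom, 1), 0.0)
        out[start:stop] = frac
    return out


@dataclass
class SequenceWeights:
    """Per-sequence phylogeny weights in (0, 1]."""

    weights: np.ndarray
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in (0, 1]")

    @property
    def N(self) -> int:
        return self.weights.size

    @classmethod
    def uniform(cls, n: int) -> "SequenceWeights":
        return cls(np.ones(n))


def compute_weights(
    msa: MSA, threshold: float = DEFAULT_IDENTITY_THRESHOLD
) -> SequenceWeights:
    """Neighborhood-inverse weights: w_a = 1 / #{b : seqid(a,b) > threshold}.

    The neighborhood count includes the sequence itself (seqid(a,a) = 1), so
    every denominator is at least 1 and isolated sequences get weight 1.
    """
    ident = pairwise_identity_matrix(msa)
    counts = (ident > threshold).sum(axis=1)
    counts = np.maximum(counts, 1)  # self identity is 1 > threshold except degenerate all-gap rows
    return SequenceWeights(1.0 / counts, identity_threshold=threshold)


def export_weights(msa: MSA, weights: SequenceWeights, path) -> None:
    with open(path, "w") as fh:
        for sid, w in zip(msa.ids, weights.weights):
            fh.write(f"{sid}\t{w:.10g}\n")


@dataclass
class PairProbabilities:
    """Weighted joint and marginal state probabilities for one column pair.

    ``joint[x, y]`` is p_ij(x, y); marginals are consistent row/column sums
    over the same included-sequence set. For the 2-letter alphabet states are
    {0, 1} (1 = matches the query residue at that column); for the 20-letter
    alphabet states index :data:`~coevnet.msa_io.AMINO_ACIDS`.
    """

    joint: np.ndarray
    p_i: np.ndarray
    p_j: np.ndarray
    n_eff: float
    alphabet: str

    @property
    def degenerate(self) -> bool:
        return self.n_eff <= 0.0


def pair_probabilities(
    msa: MSA,
    weights: SequenceWeights,
    i: int,
    j: int,
    alphabet: str = BINARY,
) -> PairProbabilities:
    """Weighted pair probabilities for 1-based columns ``i`` and ``j``.

    Sequences gapped (or carrying 'X') at either column are excluded; the
    remaining weight sum is N_eff and every probability is a weighted count
    divided by N_eff + 1.
    """
    if not (1 <= i <= msa.L and 1 <= j <= msa.L):
        raise ValueError(f"columns out of range: {i}, {j} (L={msa.L})")
    if weights.N != msa.N:
        raise ValueError("weights do not match alignment size")
    codes = msa.codes()
    ci = codes[:, i - 1]
    cj = codes[:, j - 1]
    include = (ci < GAP_CODE) & (cj < GAP_CODE)
    w = weights.weights[include]
    n_eff = float(w.sum())
    if alphabet == BINARY:
        qi = msa.codes()[msa.query_index, i - 1]
        qj = msa.codes()[msa.query_index, j - 1]
        si = (ci[include] == qi).astype(int)
        sj = (cj[include] == qj).astype(int)
        k = 2
    elif alphabet == FULL:
        si = ci[include]
        sj = cj[include]
        k = 20
    else:
        raise ValueError(f"unknown alphabet tag: {alphabet!r}")
    joint = np.zeros((k, k))
    np.add.at(joint, (si, sj), w)
    denom = n_eff + 1.0
    joint /= denom
    return PairProbabilities(
        joint=joint,
        p_i=joint.sum(axis=1),
        p_j=joint.sum(axis=0),
        n_eff=n_eff,
        alphabet=alphabet,
    )
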
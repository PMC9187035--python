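"""Synthetic alignments with planted covarying column pairs.

The generator produces query-anchored alignments whose statistical structure
exercises every stage of the pipeline:

* background columns are drawn independently per sequence from a residue
  distribution (uniform over the 20 amino acids by default, a skewed
  Robinson–Robinson-like preset is available for propensity tests);
* a planted pair (i, j, strength) couples two columns through a latent binary
  state per sequence: with probability ``strength`` both columns jointly show
  either the query residue or a fixed per-column alternative, otherwise both
  are independent background draws — strength 1.0 yields a perfectly coupled
  pair, 0.0 plain background;
* redundancy groups are blocks of near-duplicate sequences built by mutating
  a seed sequence at fewer than 20% of positions, guaranteeing > 80% mutual
  identity so the phylogenetic weighting collapses each group to total
  weight ~1;
* gaps are inserted independently per position at a configurable rate
  (default 0), exercising the N_eff exclusion logic.

All outputs are deterministic functions of the seed and the specs; matching
toy annotations and a PSI-BLAST-style profile can be emitted alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msa_io import (
    AA_INDEX,
    AMINO_ACIDS,
    GAP_CODE,
    MSA,
    FunctionalAnnotation,
    PSSMProfile,
)
from .weights import SequenceWeights, compute_weights

#: A skewed background resembling natural amino-acid abundances
#: (Robinson–Robinson-like), for tests that need non-uniform composition.
SKEWED_BACKGROUND = {
    "A": 0.078, "C": 0.019, "D": 0.054, "E": 0.063, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.051, "K": 0.057, "L": 0.090,
    "M": 0.022, "N": 0.045, "P": 0.052, "Q": 0.043, "R": 0.051,
    "S": 0.071, "T": 0.058, "V": 0.064, "W": 0.013, "Y": 0.032,
}


@dataclass(frozen=True)
class PlantedPair:
    """A planted covarying column pair (1-based columns)."""

    i: int
    j: int
    strength: float = 1.0


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated alignment."""

    planted: list[PlantedPair]
    redundancy_groups: list[list[int]]
    query: str
    seed: int
    annotated: dict[str, list[int]] = field(default_factory=dict)
    decoys: list[int] = field(default_factory=list)

    def planted_pairs(self) -> set[tuple[int, int]]:
        return {(min(p.i, p.j), max(p.i, p.j)) for p in self.planted}

    def planted_positions(self) -> list[int]:
        return sorted({k for p in self.planted for k in (p.i, p.j)})

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": [[p.i, p.j, p.strength] for p in self.planted],
            "redundancy_groups": self.redundancy_groups,
            "query": self.query,
            "seed": self.seed,
            "annotated": self.annotated,
            "decoys": self.decoys,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted=[PlantedPair(*p) for p in payload["planted"]],
            redundancy_groups=payload["redundancy_groups"],
            query=payload["query"],
            seed=payload["seed"],
            annotated={k: list(v) for k, v in payload.get("annotated", {}).items()},
            decoys=list(payload.get("decoys", [])),
        )


def _background_vector(background: dict[str, float] | None) -> np.ndarray:
    if background is None:
        return np.full(20, 1.0 / 20.0)
    vec = np.array([background.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
    if vec.sum() <= 0:
        raise ValueError("background distribution has zero mass")
    return vec / vec.sum()


def generate_msa(
    L: int = 50,
    N: int = 200,
    planted: list[tuple[int, int, float]] | list[PlantedPair] | None = None,
    redundancy: list[int] | None = None,
    background: dict[str, float] | None = None,
    gap_rate: float = 0.0,
    mutation_rate: float = 0.1,
    seed: int = 0,
) -> tuple[MSA, SyntheticTruth]:
    """Generate a query-anchored alignment with planted couplings.

    ``planted`` lists (i, j, strength) column pairs (1-based, columns must be
    distinct across pairs); ``redundancy`` lists group sizes of near-duplicate
    homologs (mutation_rate < 0.2 keeps within-group identity > 80%). The
    first sequence is the gap-free query. The same seed and specs reproduce
    the alignment byte for byte.
    """
    if L < 2 or N < 2:
        raise ValueError("require L >= 2 and N >= 2")
    if not 0 <= mutation_rate < 0.2:
        raise ValueError("mutation_rate must stay below 0.2 to keep groups > 80% identity")
    pairs = [p if isinstance(p, PlantedPair) else PlantedPair(*p) for p in (planted or [])]
    used: set[int] = set()
    for p in pairs:
        if not (1 <= p.i <= L and 1 <= p.j <= L) or p.i == p.j:
            raise ValueError(f"planted pair {p} outside columns 1..{L}")
        if not 0 <= p.strength <= 1:
            raise ValueError("coupling strength must lie in [0, 1]")
        for k in (p.i, p.j):
            if k in used:
                raise ValueError(f"column {k} appears in more than one planted pair")
            used.add(k)
    group_sizes = list(redundancy or [])
    if sum(group_sizes) > N - 1:
        raise ValueError("redundancy groups exceed the number of homologs")

    rng = np.random.default_rng(seed)
    bg = _background_vector(background)
    query_codes = rng.choice(20, size=L, p=bg)
    # per-column alternative residue for the planted latent signal (never the query's)
    alt_codes = (query_codes + 1 + rng.integers(0, 19, size=L)) % 20

    planted_cols0 = {k - 1 for k in used}  # 0-based planted columns
    n_homologs = N - 1
    rows = np.empty((n_homologs, L), dtype=np.int8)

    def fill_independent(row_idx: np.ndarray) -> None:
        block = rng.choice(20, size=(row_idx.size, L), p=bg)
        for p in pairs:
            latent = rng.random(row_idx.size) < 0.5
            coupled = rng.random(row_idx.size) < p.strength
            for col in (p.i - 1, p.j - 1):
                signal = np.where(latent, query_codes[col], alt_codes[col])
                block[:, col] = np.where(coupled, signal, block[:, col])
        rows[row_idx] = block

    # independent homologs first, then redundancy groups as mutated copies
    n_grouped = sum(group_sizes)
    independent = np.arange(0, n_homologs - n_grouped)
    if independent.size:
        fill_independent(independent)
    cursor = independent.size
    groups: list[list[int]] = []
    for size in group_sizes:
        base_idx = np.array([cursor])
        fill_independent(base_idx)
        base = rows[cursor].copy()
        members = list(range(cursor, cursor + size))
        # each member differs from the base at < mutation_rate/2 of positions so
        # any two members differ at < mutation_rate < 20%, keeping identity > 80%
        mutable = [c for c in range(L) if c not in planted_cols0]
        k = int(np.floor(mutation_rate * L / 2.0))
        for member in members[1:]:
            copy = base.copy()
            if k and mutable:
                sites = rng.choice(mutable, size=min(k, len(mutable)), replace=False)
                copy[sites] = (copy[sites] + 1 + rng.integers(0, 19, size=sites.size)) % 20
            rows[member] = copy
        groups.append([m + 1 for m in members])  # sequence indices incl. query offset
        cursor += size

    codes = np.vstack([query_codes[None, :], rows]).astype(np.int8)
    if gap_rate > 0:
        gaps = rng.random(codes.shape) < gap_rate
        gaps[0] = False  # the query stays gap-free
        codes = np.where(gaps, np.int8(GAP_CODE), codes)

    letters = np.array(list(AMINO_ACIDS + "-X"))
    sequences = ["".join(letters[row]) for row in codes]
    ids = ["query"] + [f"hom{k:04d}" for k in range(1, N)]
    msa = MSA(ids=ids, sequences=sequences, query_index=0,
              column_map=tuple(range(1, L + 1)))
    truth = SyntheticTruth(
        planted=pairs,
        redundancy_groups=groups,
        query=sequences[0],
        seed=seed,
    )
    return msa, truth


def generate_annotation(
    truth: SyntheticTruth,
    category: str = "metal",
    protein: str = "synthetic",
    decoys: int = 0,
    seed: int | None = None,
) -> FunctionalAnnotation:
    """Annotate the planted-pair columns as binding sites of one category.

    ``decoys`` extra sites are placed on background (non-planted) columns and
    recorded in the truth object.
    """
    ann = FunctionalAnnotation()
    positions = truth.planted_positions()
    for pos in positions:
        ann.add(protein, category, pos, truth.query[pos - 1])
    if decoys:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
        candidates = [k for k in range(1, len(truth.query) + 1) if k not in positions]
        chosen = sorted(rng.choice(candidates, size=min(decoys, len(candidates)),
                                   replace=False).tolist())
        for pos in chosen:
            ann.add(protein, category, pos, truth.query[pos - 1])
        truth.decoys = chosen
    truth.annotated[category] = sorted(positions + truth.decoys)
    return ann


def generate_pssm(
    msa: MSA,
    seed: int = 0,
    weights: SequenceWeights | None = None,
    background: dict[str, float] | None = None,
) -> PSSMProfile:
    """Toy log-odds profile from weighted column frequencies.

    Scores are half-bit log-odds of the weighted residue frequency (with a
    pseudo-count) against the background, rounded to integers in the
    PSI-BLAST ASCII layout; deterministic for a given alignment (``seed`` is
    part of the generator interface for reproducibility bookkeeping).
    """
    del seed  # profile is a pure function of the alignment
    if weights is None:
        weights = compute_weights(msa)
    bg = _background_vector(background)
    codes = msa.codes()
    scores = np.zeros((msa.L, 20))
    for col in range(msa.L):
        c = codes[:, col]
        keep = c < 20
        counts = np.zeros(20)
        if keep.any():
            np.add.at(counts, c[keep], weights.weights[keep])
        total = counts.sum()
        freq = (counts + bg) / (total + 1.0)  # background pseudo-counts
        scores[col] = np.clip(np.round(2.0 * np.log2(freq / bg)), -12, 12)
    query = msa.query.replace("-", "")
    return PSSMProfile(scores=scores, aa_order=AMINO_ACIDS, residues=query)
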
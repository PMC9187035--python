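"""Alignment, PSSM and binding-site annotation I/O.

Input dialects:

* query-anchored multiple sequence alignments in aligned FASTA (the first
  record is the query unless stated otherwise);
* PSI-BLAST ASCII position-specific scoring matrices (the first, log-odds,
  score block);
* ligand binding-site annotations as tab-separated records
  ``protein_id <TAB> ligand_code <TAB> position <TAB> residue`` with ``#``
  comment lines.

All residue positions exposed by this package are 1-based query coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 natural amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: k for k, a in enumerate(AMINO_ACIDS)}
GAP = "-"
UNKNOWN = "X"
#: Ambiguous / non-standard one-letter codes collapsed to 'X'.
NON_STANDARD = set("BZJUO")

# integer codes used by MSA.codes(): 0..19 amino acids, 20 gap, 21 unknown
GAP_CODE = 20
UNKNOWN_CODE = 21

#: Ligand categories and their PDB ligand codes used for benchmarking.
LIGAND_CATEGORIES: dict[str, tuple[str, ...]] = {
    "DNA/RNA": ("NUC",),
    "metal": ("CA", "CU", "FE", "FE2", "MG", "MN", "ZN"),
    "dinucleotide": ("NDP", "NAD", "NAP"),
    "nucleoside": ("ADP", "AMP", "ATP", "GDP"),
    "heme": ("HEC", "HEM"),
    "sugar": ("BGC", "FUC", "GAL", "GLC", "MAN", "NAG"),
    "coenzyme A": ("COA",),
}

LIGAND_CODE_TO_CATEGORY: dict[str, str] = {
    code: category for category, codes in LIGAND_CATEGORIES.items() for code in codes
}
# category names (case-insensitive) are accepted as codes too, so files already
# projected onto the seven categories round-trip unchanged
_CATEGORY_BY_LOWER = {c.lower(): c for c in LIGAND_CATEGORIES}


class FormatError(ValueError):
    """Malformed input file."""


class EmptyInputError(ValueError):
    """Input contains no usable records."""


def _normalize_residues(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch == ".":
            ch = GAP
        if ch in NON_STANDARD:
            ch = UNKNOWN
        if ch != GAP and ch != UNKNOWN and ch not in AA_INDEX:
            logger.warning("unrecognized residue letter %r mapped to X", ch)
            ch = UNKNOWN
        out.append(ch)
    return "".join(out)


@dataclass
class MSA:
    """A query-anchored multiple sequence alignment.

    ``sequences`` are equal-length strings over the 20 amino acids, the gap
    character ``-`` and ``X`` for unknown residues. ``column_map`` gives, for
    each column, the 1-based query position it corresponds to (populated by
    :func:`trim_to_query`; identity mapping for untrimmed alignments whose
    query happens to be gapless).
    """

    ids: list[str]
    sequences: list[str]
    query_index: int = 0
    column_map: tuple[int, ...] | None = None
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise EmptyInputError("alignment contains no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise FormatError(f"aligned records have unequal lengths: {sorted(lengths)}")
        if len(self.ids) != len(self.sequences):
            raise FormatError("number of ids does not match number of sequences")
        if self.L < 1:
            raise EmptyInputError("alignment has zero columns")
        if not 0 <= self.query_index < self.N:
            raise ValueError("query_index out of range")

    @property
    def N(self) -> int:
        return len(self.sequences)

    @property
    def L(self) -> int:
        return len(self.sequences[0])

    @property
    def query(self) -> str:
        return self.sequences[self.query_index]

    def codes(self) -> np.ndarray:
        """Integer-encoded alignment, shape (N, L): 0-19 aa, 20 gap, 21 X."""
        if self._codes is None:
            lut = np.full(128, UNKNOWN_CODE, dtype=np.int8)
            for a, k in AA_INDEX.items():
                lut[ord(a)] = k
            lut[ord(GAP)] = GAP_CODE
            buf = np.frombuffer(
                "".join(self.sequences).encode("ascii"), dtype=np.uint8
            ).reshape(self.N, self.L)
            self._codes = lut[buf]
        return self._codes


def read_alignment(path: str | Path, query_index: int = 0) -> MSA:
    """Read an aligned FASTA file into an :class:`MSA`.

    Residues are uppercased, ``.`` becomes ``-`` and non-standard letters
    (B, Z, J, U, O) become ``X``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [_normalize_residues(str(r.seq)) for r in records]
    return MSA(ids=ids, sequences=seqs, query_index=query_index)


def write_alignment(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(msa.ids, msa.sequences):
            fh.write(f">{sid}\n{seq}\n")


def trim_to_query(msa: MSA) -> MSA:
    """Remove every column where the query carries a gap.

    The resulting alignment length equals the ungapped query length and
    ``column_map`` records the 1-based query position of each kept column.
    Idempotent: a gapless query passes through unchanged.
    """
    keep = [k for k, ch in enumerate(msa.query) if ch != GAP]
    if not keep:
        raise EmptyInputError("query sequence is all gaps")
    if len(keep) == msa.L:
        if msa.column_map is None:
            return MSA(
                ids=list(msa.ids),
                sequences=list(msa.sequences),
                query_index=msa.query_index,
                column_map=tuple(range(1, msa.L + 1)),
            )
        return msa
    seqs = ["".join(s[k] for k in keep) for s in msa.sequences]
    return MSA(
        ids=list(msa.ids),
        sequences=seqs,
        query_index=msa.query_index,
        column_map=tuple(range(1, len(keep) + 1)),
    )


@dataclass
class PSSMProfile:
    """Position-specific scores for the (trimmed) query.

    ``scores`` is L x 20 in ``aa_order`` column order; ``residues`` is the
    query residue printed beside each row. Weighted per-position means and
    standard deviations of realized substitution scores are computed by the
    covariance layer and may be cached here.
    """

    scores: np.ndarray
    aa_order: str = AMINO_ACIDS
    residues: str | None = None
    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise FormatError("PSSM must have 20 score columns")
        if len(set(self.aa_order)) != 20:
            raise FormatError("aa_order must list 20 distinct amino acids")

    @property
    def L(self) -> int:
        return self.scores.shape[0]

    def score(self, position: int, amino_acid: str) -> float:
        """Score of ``amino_acid`` at 1-based query ``position``."""
        return float(self.scores[position - 1, self.aa_order.index(amino_acid)])

    def reordered(self, aa_order: str = AMINO_ACIDS) -> "PSSMProfile":
        idx = [self.aa_order.index(a) for a in aa_order]
        return PSSMProfile(self.scores[:, idx], aa_order, self.residues)


def read_pssm(path: str | Path, query: str | None = None) -> PSSMProfile:
    """Parse the log-odds block of a PSI-BLAST ASCII PSSM.

    The header line holds the 20-letter column order (possibly twice when the
    weighted-percentage block is present); only the first 20 integer columns
    of each row are used. If ``query`` is given, row count and row residue
    letters are checked against it.
    """
    aa_order: str | None = None
    rows: list[list[float]] = []
    residues: list[str] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            if aa_order is None:
                if len(tokens) >= 20 and all(t in AA_INDEX for t in tokens[:20]):
                    aa_order = "".join(tokens[:20])
                continue
            if not tokens[0].isdigit():
                continue  # trailing K/lambda statistics
            if len(tokens) < 22:
                raise FormatError(f"unparsable PSSM row: {line.rstrip()!r}")
            try:
                scores = [float(t) for t in tokens[2:22]]
            except ValueError as exc:
                raise FormatError(f"unparsable PSSM row: {line.rstrip()!r}") from exc
            rows.append(scores)
            residues.append(tokens[1])
    if aa_order is None or not rows:
        raise FormatError(f"no PSSM score block found in {path}")
    profile = PSSMProfile(np.array(rows), aa_order, "".join(residues))
    if query is not None:
        ungapped = query.replace(GAP, "")
        if profile.L != len(ungapped):
            raise FormatError(
                f"PSSM has {profile.L} rows but query has {len(ungapped)} residues"
            )
        for k, (a, b) in enumerate(zip(profile.residues, ungapped), start=1):
            if a != b and UNKNOWN not in (a, b):
                raise FormatError(f"PSSM residue mismatch at position {k}: {a} vs {b}")
    return profile


def write_pssm(profile: PSSMProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect read by :func:`read_pssm`."""
    residues = profile.residues or "X" * profile.L
    with open(path, "w") as fh:
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("      " + "  ".join(profile.aa_order) + "\n")
        for k in range(profile.L):
            cells = " ".join(f"{int(round(v)):3d}" for v in profile.scores[k])
            fh.write(f"{k + 1:5d} {residues[k]} {cells}\n")


@dataclass
class FunctionalAnnotation:
    """Ligand binding sites: protein -> category -> {1-based position: residue}."""

    sites: dict[str, dict[str, dict[int, str]]] = field(default_factory=dict)
    skipped: int = 0

    def add(self, protein: str, category: str, position: int, residue: str = UNKNOWN) -> None:
        if position < 1:
            raise FormatError(f"non-positive residue position {position}")
        self.sites.setdefault(protein, {}).setdefault(category, {})[position] = residue

    def positions(self, protein: str, category: str) -> list[int]:
        return sorted(self.sites.get(protein, {}).get(category, {}))

    def proteins(self) -> list[str]:
        return sorted(self.sites)

    def categories(self) -> list[str]:
        found = {c for per_protein in self.sites.values() for c in per_protein}
        return sorted(found)

    def records(self) -> Iterable[tuple[str, str, int, str]]:
        for protein in sorted(self.sites):
            for category in sorted(self.sites[protein]):
                for pos, res in sorted(self.sites[protein][category].items()):
                    yield protein, category, pos, res


def resolve_ligand_category(code: str) -> str | None:
    """Map a PDB ligand code (or a category name) to its ligand category."""
    cat = LIGAND_CODE_TO_CATEGORY.get(code.upper())
    if cat is not None:
        return cat
    return _CATEGORY_BY_LOWER.get(code.lower())


def read_annotations(
    path: str | Path,
    code_map: Mapping[str, str] | None = None,
) -> FunctionalAnnotation:
    """Read binding-site TSV records, collapsing ligand codes to categories.

    Unknown ligand codes are skipped with a warning (count kept on the
    returned object); duplicate (protein, category, position) records are
    deduplicated.
    """
    ann = FunctionalAnnotation()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: expected at least 3 columns")
            protein, code, pos_s = fields[0], fields[1], fields[2]
            residue = fields[3] if len(fields) > 3 else UNKNOWN
            try:
                position = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: bad position {pos_s!r}") from exc
            if position < 1:
                raise FormatError(f"{path}:{ln}: non-positive position {position}")
            category = (code_map or {}).get(code) or resolve_ligand_category(code)
            if category is None:
                logger.warning("%s:%d: unknown ligand code %r skipped", path, ln, code)
                ann.skipped += 1
                continue
            ann.add(protein, category, position, residue.upper()[:1] or UNKNOWN)
    return ann


def write_annotations(ann: FunctionalAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_id\tligand_category\tposition\tresidue\n")
        for protein, category, pos, res in ann.records():
            fh.write(f"{protein}\t{category}\t{pos}\t{res}\n")


@dataclass(frozen=True)
class BenchmarkCandidate:
    """A protein considered for the non-redundant benchmark set."""

    id: str
    sequence: str
    n_homologs: int


def _default_identity(a: str, b: str) -> float:
    """Global pairwise identity: identical aligned positions / longer length."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    matches = aligner.score(a.replace(GAP, ""), b.replace(GAP, ""))
    return float(matches) / max(len(a), len(b))


def apply_benchmark_filters(
    candidates: Sequence[BenchmarkCandidate],
    min_length: int = 30,
    min_homologs: int = 100,
    max_identity: float = 0.25,
    identity_fn: Callable[[str, str], float] | None = None,
) -> list[BenchmarkCandidate]:
    """Greedy benchmark filtering: length >= 30 aa, >= 100 homology hits, and
    pairwise identity to every already retained protein < 25% (input order)."""
    identity = identity_fn or _default_identity
    kept: list[BenchmarkCandidate] = []
    for cand in candidates:
        if len(cand.sequence) < min_length:
            continue
        if cand.n_homologs < min_homologs:
            continue
        if any(identity(cand.sequence, k.sequence) >= max_identity for k in kept):
            continue
        kept.append(cand)
    return kept
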
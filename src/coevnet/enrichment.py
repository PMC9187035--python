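"""Functional-site enrichment: log-odds coupling scores, propensities,
distance distributions and benchmark summaries.

For a residue i annotated with molecular function f, the log-odds score

    LO_i^f = ln[ (r / (R_f - 1)) / (n / (N - 1)) ]

measures the enrichment of same-function residues among i's covarying
partners: n counts all positions j != i whose coupling with i reaches the
cutoff, r counts those that share f, R_f is the number of f-residues in the
protein and N the protein length (both corrected for the residue of
interest). LO is undefined (NA) whenever a logarithm argument is zero or
undefined, i.e. r = 0, n = 0 or R_f <= 1.

The clique variant LO(q) replaces the covarying-neighborhood counts with the
membership of a maximal clique containing i: n = |q| - 1 and r = same-function
members. Clique members need not themselves be directly coupled to i above
the cutoff.

P(LO) is the empirical survival fraction of a pooled LO sample at a given LO
cutoff. Amino-acid binding propensities are P(a|l) = ln(f_{a,l} / F_a), the
log-ratio of an amino acid's frequency among sites binding ligand l to its
background frequency in the protein set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .covariance import CovarianceMatrix
from .graphs import build_graph, maximal_cliques
from .msa_io import AMINO_ACIDS, FunctionalAnnotation

logger = logging.getLogger(__name__)

DEFAULT_DISTANCE_BINS = ((1, 4), (5, 29), (30, 1000))


@dataclass(frozen=True)
class LogOdds:
    """One LO evaluation with the counts behind it; ``lo`` is None when NA."""

    lo: float | None
    count_same_function: int  # r
    count_covarying: int  # n
    total_function: int  # R_f
    protein_length: int  # N

    @property
    def is_na(self) -> bool:
        return self.lo is None


def _log_odds(r: int, n: int, R_f: int, N: int) -> LogOdds:
    if not 0 <= r <= n:
        raise ValueError("require 0 <= r <= n")
    if n > N - 1 or (R_f >= 1 and r > R_f - 1):
        raise ValueError("counts exceed protein bounds")
    if r == 0 or n == 0 or R_f <= 1:
        return LogOdds(None, r, n, R_f, N)
    lo = math.log((r / (R_f - 1)) / (n / (N - 1)))
    return LogOdds(lo, r, n, R_f, N)


def lo_score(
    i: int,
    matrix: CovarianceMatrix,
    functional_positions: Iterable[int],
    cutoff: float,
    protein_length: int | None = None,
) -> LogOdds:
    """Neighborhood LO for annotated residue ``i`` (1-based).

    ``functional_positions`` are all positions annotated with the same
    function, ``i`` included. Masked couplings count as below any cutoff.
    """
    sites = set(functional_positions)
    if i not in sites:
        raise ValueError(f"residue {i} is not among the annotated positions")
    N = protein_length if protein_length is not None else matrix.L
    row = matrix.values[i - 1]
    mask = matrix.mask[i - 1]
    covarying = {
        j + 1
        for j in range(matrix.L)
        if j + 1 != i and not mask[j] and row[j] >= cutoff
    }
    n = len(covarying)
    r = len(covarying & (sites - {i}))
    return _log_odds(r, n, len(sites), N)


def lo_clique(
    i: int,
    clique: Iterable[int],
    functional_positions: Iterable[int],
    protein_length: int,
) -> LogOdds:
    """Clique LO: counts run over the clique's members instead of i's
    direct covarying neighborhood."""
    members = set(clique)
    if i not in members:
        raise ValueError(f"residue {i} is not a member of the clique")
    sites = set(functional_positions)
    n = len(members) - 1
    r = len((members - {i}) & (sites - {i}))
    return _log_odds(r, n, len(sites), protein_length)


def p_lo(lo_values: Iterable[float | None | LogOdds], lo_cutoff: float) -> float | None:
    """Empirical survival fraction of finite LO values at ``lo_cutoff``.

    NA values are excluded; returns None when no finite value remains.
    """
    finite = []
    for v in lo_values:
        if isinstance(v, LogOdds):
            v = v.lo
        if v is None or not math.isfinite(v):
            continue
        finite.append(v)
    if not finite:
        return None
    return sum(1 for v in finite if v >= lo_cutoff) / len(finite)


@dataclass
class PropensityTable:
    """ln(f_{a,l} / F_a) per amino acid and ligand category."""

    propensity: pd.DataFrame  # 20 x categories, NaN = NA
    site_fraction: pd.DataFrame  # f_{a,l}
    background: pd.Series  # F_a

    def value(self, amino_acid: str, category: str) -> float:
        return float(self.propensity.loc[amino_acid, category])


def propensity_table(
    annotation: FunctionalAnnotation,
    sequences: Mapping[str, str],
) -> PropensityTable:
    """Binding propensities pooled across proteins.

    ``sequences`` maps protein id to its (ungapped) sequence; the background
    frequency F_a is taken over all residues of all sequences. Annotated
    residue letters are checked against the sequences, mismatches logged.
    Cells with zero observations are NA.
    """
    bg_counts = pd.Series(0.0, index=list(AMINO_ACIDS))
    for seq in sequences.values():
        for ch in seq:
            if ch in bg_counts.index:
                bg_counts[ch] += 1
    if bg_counts.sum() == 0:
        raise ValueError("no background residues available")
    background = bg_counts / bg_counts.sum()

    categories = annotation.categories()
    site_counts = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=categories)
    mismatches = 0
    for protein, category, pos, recorded in annotation.records():
        seq = sequences.get(protein)
        if seq is None or pos > len(seq):
            logger.warning("annotation %s:%d outside available sequence", protein, pos)
            continue
        actual = seq[pos - 1]
        if recorded != "X" and recorded != actual:
            mismatches += 1
            logger.warning(
                "annotation residue mismatch %s:%d: recorded %s, sequence has %s",
                protein, pos, recorded, actual,
            )
        if actual in site_counts.index:
            site_counts.loc[actual, category] += 1
    if mismatches:
        logger.info("%d annotation residue-letter mismatches", mismatches)

    totals = site_counts.sum(axis=0)
    site_fraction = site_counts / totals.replace(0, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.log(site_fraction.div(background, axis=0))
    prop = prop.where(site_fraction > 0)  # zero-observation cells are NA
    return PropensityTable(propensity=prop, site_fraction=site_fraction, background=background)


def distance_distribution(
    annotation: FunctionalAnnotation,
    bins: Sequence[tuple[int, int]] = DEFAULT_DISTANCE_BINS,
    all_pairs: bool = False,
) -> pd.DataFrame:
    """Percentage distribution of sequence separations between same-category sites.

    Separations are differences between consecutive sorted positions within
    each protein and category (``all_pairs=True`` switches to every pair),
    pooled across proteins; distances beyond the last bin are clamped into
    it. Each category column sums to 100; categories with no pair are NA.
    """
    labels = [f"{a}-{b}" for a, b in bins]
    categories = annotation.categories()
    counts = pd.DataFrame(0.0, index=labels, columns=categories)
    for protein in annotation.proteins():
        for category, per_pos in annotation.sites[protein].items():
            positions = sorted(per_pos)
            if len(positions) < 2:
                continue
            if all_pairs:
                deltas = [
                    positions[b] - positions[a]
                    for a in range(len(positions))
                    for b in range(a + 1, len(positions))
                ]
            else:
                deltas = [b - a for a, b in zip(positions, positions[1:])]
            for d in deltas:
                d = min(d, bins[-1][1])  # clamp into the last bin
                for (lo, hi), label in zip(bins, labels):
                    if lo <= d <= hi:
                        counts.loc[label, category] += 1
                        break
    totals = counts.sum(axis=0)
    return 100.0 * counts / totals.replace(0, np.nan)


def benchmark_summary(annotation: FunctionalAnnotation) -> pd.Series:
    """Distinct (protein, position) residue counts per ligand category."""
    counts: dict[str, set[tuple[str, int]]] = {}
    for protein, category, pos, _res in annotation.records():
        counts.setdefault(category, set()).add((protein, pos))
    return pd.Series(
        {c: len(v) for c, v in sorted(counts.items())}, dtype=int, name="residues"
    )


def protein_lo_report(
    matrix: CovarianceMatrix,
    annotation: FunctionalAnnotation,
    protein: str,
    cutoffs: Sequence[float],
    mode: str = "neighbors",
    protein_length: int | None = None,
    min_separation: int = 1,
) -> pd.DataFrame:
    """Per-residue, per-cutoff LO table for one protein.

    Rows are annotated residues (position, residue, category); one column per
    cutoff holds LO or NaN. ``mode="neighbors"`` uses the covarying
    neighborhood; ``mode="clique"`` uses maximal cliques of the thresholded
    graph, reporting for each residue the maximum LO over the maximal cliques
    containing it (NA if it sits in none).
    """
    if mode not in ("neighbors", "clique"):
        raise ValueError(f"unknown mode {mode!r}")
    N = protein_length if protein_length is not None else matrix.L
    per_protein = annotation.sites.get(protein, {})
    rows = []
    index = []
    if not per_protein:
        logger.warning("no annotated residues for protein %r", protein)
    clique_sets = {}
    if mode == "clique":
        for c in cutoffs:
            g = build_graph(matrix, c, min_separation=min_separation)
            clique_sets[c] = maximal_cliques(g)
    for category in sorted(per_protein):
        sites = sorted(per_protein[category])
        for pos in sites:
            residue = per_protein[category][pos]
            if matrix.residues and pos <= len(matrix.residues):
                residue = matrix.residues[pos - 1]
            cells = {}
            for c in cutoffs:
                if mode == "neighbors":
                    result = lo_score(pos, matrix, sites, c, protein_length=N)
                    cells[c] = np.nan if result.is_na else result.lo
                else:
                    best = np.nan
                    for clique in clique_sets[c].containing(pos):
                        res = lo_clique(pos, clique, sites, protein_length=N)
                        if not res.is_na and (np.isnan(best) or res.lo > best):
                            best = res.lo
                    cells[c] = best
            rows.append({"residue": residue, "category": category, **cells})
            index.append(pos)
    df = pd.DataFrame(rows, index=pd.Index(index, name="position"))
    return df


def write_lo_report(report: pd.DataFrame, path) -> None:
    out = report.copy()
    out.to_csv(path, sep="\t", na_rep="NA")


def write_propensities(table: PropensityTable, path) -> None:
    table.propensity.round(4).to_csv(path, sep="\t", na_rep="NA")


def write_distances(dist: pd.DataFrame, path) -> None:
    dist.round(2).to_csv(path, sep="\t", na_rep="NA")
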
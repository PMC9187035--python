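"""Pairwise column covariance metrics over a weighted alignment.

Three coupling statistics between alignment columns i and j are implemented,
all computed from the sub-normalized, phylogeny-weighted pair probabilities
of :mod:`coevnet.weights`:

* mutual information,  MI(i,j) = sum_xy p_ij(x,y) ln[ p_ij(x,y) / (p_i(x) p_j(y)) ];
* a chi-squared statistic, chi2(i,j) = sum_xy (p_ij - p_i p_j)^2 / (p_i p_j),
  post-processed through the chi-squared(df=1) lower-tail CDF into [0, 1];
* a Pearson correlation over PSI-BLAST substitution scores,
  r(i,j) = (1/N_eff) sum_l w_l (s_il - mean_i)(s_jl - mean_j) / (sd_i sd_j),
  reported as |r|.

MI and chi2 run on either the 2-letter (match/mismatch to the query residue)
or the 20-letter alphabet; the Pearson metric is score-based and alphabet
free. Pairs where no sequence carries residues at both columns (N_eff = 0),
or where a column's realized scores are constant (sd = 0, Pearson only), are
masked and exported as "NA".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .msa_io import GAP_CODE, MSA, PSSMProfile, AMINO_ACIDS
from .weights import (
    BINARY,
    FULL,
    PairProbabilities,
    SequenceWeights,
    compute_weights,
)

METRIC_MI = "mi"
METRIC_CHI2 = "chi2"
METRIC_PEARSON = "pearson"
METRICS = (METRIC_MI, METRIC_CHI2, METRIC_PEARSON)


def mutual_information(probs: PairProbabilities) -> float:
    """Natural-log mutual information; zero-probability joint states contribute 0."""
    if probs.degenerate:
        raise ValueError("degenerate pair: N_eff = 0")
    joint = probs.joint
    expected = np.outer(probs.p_i, probs.p_j)
    pos = joint > 0
    return float(np.sum(joint[pos] * np.log(joint[pos] / expected[pos])))


def chi_squared(probs: PairProbabilities) -> float:
    """Chi-squared departure from independence on the weighted probabilities.

    States with zero expected probability p_i(x) p_j(y) are skipped.
    """
    if probs.degenerate:
        raise ValueError("degenerate pair: N_eff = 0")
    joint = probs.joint
    expected = np.outer(probs.p_i, probs.p_j)
    pos = expected > 0
    return float(np.sum((joint[pos] - expected[pos]) ** 2 / expected[pos]))


def chi2_to_probability(chi2: float | np.ndarray):
    """Lower-tail chi-squared (df = 1) CDF, mapping scores to [0, 1]."""
    arr = np.asarray(chi2, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("chi-squared scores must be non-negative")
    out = stats.chi2.cdf(arr, df=1)
    return float(out) if np.isscalar(chi2) else out


def _realized_scores(msa: MSA, pssm: PSSMProfile) -> np.ndarray:
    """N x L matrix of PSSM scores realized by each aligned residue; NaN at gaps/X."""
    prof = pssm if pssm.aa_order == AMINO_ACIDS else pssm.reordered(AMINO_ACIDS)
    if prof.L != msa.L:
        raise ValueError(f"PSSM rows ({prof.L}) do not match alignment columns ({msa.L})")
    codes = msa.codes()
    valid = codes < GAP_CODE
    safe = np.where(valid, codes, 0)
    scores = prof.scores[np.arange(msa.L)[None, :], safe]
    return np.where(valid, scores, np.nan)


def pearson_covariance(
    msa: MSA,
    pssm: PSSMProfile,
    weights: SequenceWeights,
    i: int,
    j: int,
) -> float | None:
    """|r| between realized substitution scores at columns i and j (1-based).

    Means and standard deviations are weighted population statistics over the
    sequences carrying residues at both columns. Returns ``None`` (masked)
    when the pair is degenerate or either column's scores are constant.
    """
    s = _realized_scores(msa, pssm)
    return _pearson_from_scores(s[:, i - 1], s[:, j - 1], weights.weights)


def _pearson_from_scores(si: np.ndarray, sj: np.ndarray, w: np.ndarray) -> float | None:
    include = ~np.isnan(si) & ~np.isnan(sj)
    if not include.any():
        return None
    wi = w[include]
    n_eff = wi.sum()
    if n_eff <= 0:
        return None
    x = si[include]
    y = sj[include]
    mx = float(np.dot(wi, x) / n_eff)
    my = float(np.dot(wi, y) / n_eff)
    sx = float(np.sqrt(np.dot(wi, (x - mx) ** 2) / n_eff))
    sy = float(np.sqrt(np.dot(wi, (y - my) ** 2) / n_eff))
    if sx <= 0 or sy <= 0:
        return None
    r = float(np.dot(wi, (x - mx) * (y - my)) / (n_eff * sx * sy))
    return abs(max(-1.0, min(1.0, r)))


@dataclass
class CovarianceMatrix:
    """L x L symmetric coupling scores with degenerate-pair mask and provenance.

    ``mask[i, j]`` is True where the score is undefined; masked entries hold
    NaN in ``values`` and export as "NA". Positions are 1-based query
    coordinates throughout.
    """

    values: np.ndarray
    metric: str
    alphabet: str | None = None
    post_processed: bool = True
    mask: np.ndarray | None = None
    residues: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("covariance matrix must be square")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        finite = self.values[~self.mask]
        if finite.size and not np.allclose(
            np.where(self.mask, 0.0, np.nan_to_num(self.values)),
            np.where(self.mask.T, 0.0, np.nan_to_num(self.values.T)),
            atol=1e-12,
            rtol=0,
        ):
            raise ValueError("covariance matrix must be symmetric")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    def score(self, i: int, j: int) -> float:
        """Score for 1-based positions; NaN when masked."""
        if self.mask[i - 1, j - 1]:
            return float("nan")
        return float(self.values[i - 1, j - 1])

    def off_diagonal_max(self) -> float:
        vals = np.where(self.mask, -np.inf, self.values).copy()
        np.fill_diagonal(vals, -np.inf)
        return float(vals.max())


def _binary_metric_matrices(
    msa: MSA, weights: SequenceWeights
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized MI and chi2 matrices on the 2-letter alphabet.

    Returns (mi, chi2, n_eff) as L x L arrays; entries with N_eff = 0 are NaN.
    Uses the identity that for the match/mismatch encoding all pairwise joint
    counts reduce to four matrix products over the N x L indicator matrices.
    """
    codes = msa.codes()
    valid = (codes < GAP_CODE).astype(float)
    match = (codes == codes[msa.query_index][None, :]).astype(float) * valid
    w = weights.weights[:, None]
    wv = w * valid
    wm = w * match
    n_eff = wv.T @ valid  # sum of weights where both columns valid
    c11 = wm.T @ match
    mi1 = wm.T @ valid  # weighted count of state 1 at i over the pair's included set
    mj1 = wv.T @ match
    denom = n_eff + 1.0
    p11 = c11 / denom
    p10 = (mi1 - c11) / denom
    p01 = (mj1 - c11) / denom
    p00 = (n_eff - mi1 - mj1 + c11) / denom
    pi1, pi0 = mi1 / denom, (n_eff - mi1) / denom
    pj1, pj0 = mj1 / denom, (n_eff - mj1) / denom

    mi = np.zeros_like(p11)
    chi2 = np.zeros_like(p11)
    for joint, px, py in (
        (p11, pi1, pj1),
        (p10, pi1, pj0),
        (p01, pi0, pj1),
        (p00, pi0, pj0),
    ):
        expected = px * py
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(joint > 0, joint * np.log(np.where(joint > 0, joint, 1.0) / np.where(expected > 0, expected, 1.0)), 0.0)
            mi += np.where(expected > 0, term, 0.0)
            chi2 += np.where(expected > 0, (joint - expected) ** 2 / np.where(expected > 0, expected, 1.0), 0.0)
    degenerate = n_eff <= 0
    mi[degenerate] = np.nan
    chi2[degenerate] = np.nan
    return mi, chi2, n_eff


def covariance_matrix(
    msa: MSA,
    metric: str,
    alphabet: str = BINARY,
    pssm: PSSMProfile | None = None,
    weights: SequenceWeights | None = None,
    post_process: bool = True,
) -> CovarianceMatrix:
    """All-pairs coupling matrix for one metric.

    Post-processing (on by default) maps chi2 scores through the
    chi-squared(df=1) CDF; Pearson scores are always reported as |r|.
    Diagonal entries are computed and exported but are excluded from graphs,
    cliques and enrichment counting downstream.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if metric == METRIC_PEARSON and pssm is None:
        raise ValueError("the pearson metric requires a PSSM")
    if weights is None:
        weights = compute_weights(msa)
    L = msa.L
    values = np.full((L, L), np.nan)

    if metric == METRIC_PEARSON:
        s = _realized_scores(msa, pssm)
        for i in range(L):
            for j in range(i, L):
                r = _pearson_from_scores(s[:, i], s[:, j], weights.weights)
                values[i, j] = values[j, i] = np.nan if r is None else r
        n_eff_summary = None
        alphabet = None
    elif alphabet == BINARY:
        mi, chi2, n_eff = _binary_metric_matrices(msa, weights)
        values = mi if metric == METRIC_MI else chi2
        n_eff_summary = float(np.median(n_eff))
    else:
        from .weights import pair_probabilities

        n_effs = []
        for i in range(L):
            for j in range(i, L):
                probs = pair_probabilities(msa, weights, i + 1, j + 1, alphabet)
                if probs.degenerate:
                    score = np.nan
                else:
                    score = (
                        mutual_information(probs)
                        if metric == METRIC_MI
                        else chi_squared(probs)
                    )
                values[i, j] = values[j, i] = score
                n_effs.append(probs.n_eff)
        n_eff_summary = float(np.median(n_effs)) if n_effs else 0.0

    mask = np.isnan(values)
    if post_process and metric == METRIC_CHI2:
        values = np.where(mask, np.nan, chi2_to_probability(np.where(mask, 0.0, values)))
        values[mask] = np.nan
    meta = {"metric": metric, "N": msa.N, "post_processed": post_process}
    if alphabet is not None:
        meta["alphabet"] = alphabet
    if n_eff_summary is not None:
        meta["n_eff_median"] = n_eff_summary
    residues = None
    if msa.query and "-" not in msa.query:
        residues = msa.query
    return CovarianceMatrix(
        values=values,
        metric=metric,
        alphabet=alphabet,
        post_processed=post_process if metric != METRIC_MI else False,
        mask=mask,
        residues=residues,
        meta=meta,
    )


def write_matrix(matrix: CovarianceMatrix, path: str | Path) -> None:
    """Square TSV with 1-based position headers, "NA" for masked entries.

    A ``<path>.meta`` sidecar records metric, alphabet and provenance as
    key=value lines.
    """
    L = matrix.L
    with open(path, "w") as fh:
        fh.write("pos\t" + "\t".join(str(k + 1) for k in range(L)) + "\n")
        for i in range(L):
            cells = [
                "NA" if matrix.mask[i, j] else f"{matrix.values[i, j]:.10g}"
                for j in range(L)
            ]
            fh.write(f"{i + 1}\t" + "\t".join(cells) + "\n")
    with open(str(path) + ".meta", "w") as fh:
        fh.write(f"metric={matrix.metric}\n")
        if matrix.alphabet:
            fh.write(f"alphabet={matrix.alphabet}\n")
        fh.write(f"post_processed={matrix.post_processed}\n")
        if matrix.residues:
            fh.write(f"query={matrix.residues}\n")
        for key, val in matrix.meta.items():
            if key not in {"metric", "alphabet", "post_processed"}:
                fh.write(f"{key}={val}\n")


def read_matrix(path: str | Path) -> CovarianceMatrix:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("pos"):
            raise ValueError(f"{path}: not a covariance matrix TSV")
        for line in fh:
            cells = line.rstrip("\n").split("\t")[1:]
            rows.append([np.nan if c == "NA" else float(c) for c in cells])
    meta: dict = {}
    metric = "unknown"
    alphabet = None
    post = True
    residues = None
    meta_path = Path(str(path) + ".meta")
    if meta_path.exists():
        for line in meta_path.read_text().splitlines():
            if "=" not in line:
                continue
            key, _, val = line.partition("=")
            if key == "metric":
                metric = val
            elif key == "alphabet":
                alphabet = val
            elif key == "post_processed":
                post = val == "True"
            elif key == "query":
                residues = val
            else:
                meta[key] = val
    values = np.array(rows)
    return CovarianceMatrix(
        values=values,
        metric=metric,
        alphabet=alphabet,
        post_processed=post,
        mask=np.isnan(values),
        residues=residues,
        meta=meta,
    )
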
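"""Mutual information and mean-field DCA direct information from an MSA.

Both metrics are computed on the TMD columns of the homologue alignment with
the classic mean-field direct-coupling-analysis preprocessing: sequences are
reweighted by the inverse size of their 80%-identity neighbourhood, and
frequencies are regularised with a pseudocount proportional to the effective
sequence count.  Direct information is the Kullback-Leibler divergence of the
two-site "direct" distribution (couplings from the negative inverse of the
covariance matrix, fields fitted so the two-site model reproduces the single
site marginals) from the product of its marginals.

Per-residue summary features reduce the L x L matrix to row statistics (max,
top-k means, neighbour-window means, ...), each emitted raw and min-max
normalised within the TMD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import errors
from .msa_features import Alignment

ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"  # 21 states, gap last
Q = len(ALPHABET)
_CHAR_TO_STATE = {c: i for i, c in enumerate(ALPHABET)}

#: Row-summary statistics of a coevolution matrix, in emission order.
SUMMARY_NAMES = (
    "max",
    "top2mean",
    "top3mean",
    "top4mean",
    "top8mean",
    "mean",
    "median",
    "std",
    "mean_nb1",
    "mean_nb2",
    "mean_nb3",
    "mean_nb4",
    "max_nb4",
)


@dataclass
class DcaParams:
    """Mean-field DCA preprocessing parameters.

    ``theta``: fractional identity above which sequences share weight
    (reweighting neighbourhood).  ``pseudocount``: pseudocount weight as a
    fraction of the effective sequence count (lambda = pseudocount * M_eff).
    """

    theta: float = 0.8
    pseudocount: float = 0.5

    def __post_init__(self):
        if not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass
class CoevolutionMatrix:
    """L x L symmetric coevolution matrix with a zero diagonal."""

    metric: str  # "MI" or "DI"
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("coevolution matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("coevolution matrix must be symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v

    def __len__(self):
        return self.values.shape[0]


def encode_alignment(aln: Alignment) -> np.ndarray:
    """Integer state matrix (valid rows x TMD columns) over the 21-state alphabet."""
    mat = aln.tmd_matrix(valid_only=True)
    out = np.empty(mat.shape, dtype=np.int8)
    for ch, s in _CHAR_TO_STATE.items():
        out[mat == ch] = s
    unknown = ~np.isin(mat, list(ALPHABET))
    out[unknown] = Q - 1  # treat unknowns as gaps
    return out


def sequence_weights(states: np.ndarray, theta: float) -> np.ndarray:
    """1 / (number of sequences within fractional identity >= theta)."""
    m, length = states.shape
    sim = np.zeros((m, m), dtype=int)
    for i in range(m):
        sim[i] = (states == states[i]).sum(axis=1)
    neighbours = (sim >= theta * length).sum(axis=1)
    return 1.0 / neighbours


def _frequencies(states: np.ndarray, weights: np.ndarray, pseudocount: float):
    """Regularised single- and pair-site frequencies (fi: L x q, fij: L x L x q x q)."""
    m, length = states.shape
    meff = weights.sum()
    lam = pseudocount * meff
    onehot = np.zeros((m, length, Q))
    onehot[np.arange(m)[:, None], np.arange(length)[None, :], states] = 1.0
    fi = (lam / Q + np.einsum("s,sia->ia", weights, onehot)) / (meff + lam)
    flat = onehot.reshape(m, length * Q)
    pair_counts = flat.T @ (flat * weights[:, None])
    fij = pair_counts.reshape(length, Q, length, Q).transpose(0, 2, 1, 3)
    fij = (lam / Q**2 + fij) / (meff + lam)
    # the diagonal blocks describe a single site: fij(i,i,a,b) = delta_ab fi(i,a)
    for i in range(length):
        fij[i, i] = np.diag(fi[i])
    return fi, fij, meff


def mi_matrix(aln: Alignment, params: DcaParams | None = None) -> CoevolutionMatrix:
    """Pairwise mutual information (bits) with DCA-style weighting/regularisation."""
    params = params or DcaParams()
    states = encode_alignment(aln)
    if states.shape[0] < 2:
        raise errors.InsufficientDepthError("mutual information needs >= 2 valid rows")
    w = sequence_weights(states, params.theta)
    fi, fij, _ = _frequencies(states, w, params.pseudocount)
    length = states.shape[1]
    mi = np.zeros((length, length))
    for i in range(length):
        for j in range(i + 1, length):
            pij = fij[i, j]
            indep = np.outer(fi[i], fi[j])
            mask = pij > 0
            mi[i, j] = mi[j, i] = float(
                (pij[mask] * np.log2(pij[mask] / indep[mask])).sum()
            )
    return CoevolutionMatrix("MI", mi)


def _two_site_direct(w_ij: np.ndarray, fi: np.ndarray, fj: np.ndarray,
                     tol: float = 1e-10, max_iter: int = 5000,
                     damping: float = 0.5) -> np.ndarray:
    """Two-site direct distribution: P(a,b) ~ W(a,b) mu1(a) mu2(b).

    The auxiliary fields mu1/mu2 are fitted so the marginals of P match fi
    and fj, by damped Gauss-Seidel iteration (the undamped simultaneous
    update can oscillate).
    """
    mu1 = np.full(Q, 1.0 / Q)
    mu2 = np.full(Q, 1.0 / Q)
    for _ in range(max_iter):
        new1 = fi / (w_ij @ mu2)
        new1 /= new1.sum()
        mu1_next = damping * mu1 + (1 - damping) * new1
        new2 = fj / (w_ij.T @ mu1_next)
        new2 /= new2.sum()
        mu2_next = damping * mu2 + (1 - damping) * new2
        delta = max(np.abs(mu1_next - mu1).max(), np.abs(mu2_next - mu2).max())
        mu1, mu2 = mu1_next, mu2_next
        if delta < tol:
            break
    p = w_ij * np.outer(mu1, mu2)
    return p / p.sum()


def di_matrix(aln: Alignment, params: DcaParams | None = None) -> CoevolutionMatrix:
    """Direct information via mean-field DCA (naive mean-field inversion)."""
    params = params or DcaParams()
    states = encode_alignment(aln)
    if states.shape[0] < 2:
        raise errors.InsufficientDepthError("direct information needs >= 2 valid rows")
    w = sequence_weights(states, params.theta)
    fi, fij, _ = _frequencies(states, w, params.pseudocount)
    length = states.shape[1]
    q1 = Q - 1  # gauge: last state carries zero couplings
    cov = np.empty((length * q1, length * q1))
    for i in range(length):
        for j in range(length):
            block = fij[i, j, :q1, :q1] - np.outer(fi[i, :q1], fi[j, :q1])
            cov[i * q1:(i + 1) * q1, j * q1:(j + 1) * q1] = block
    try:
        inv_cov = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise errors.NumericConditioningError(
            "covariance matrix is singular; raise the pseudocount weight"
        ) from exc
    di = np.zeros((length, length))
    for i in range(length):
        for j in range(i + 1, length):
            e_ij = np.zeros((Q, Q))
            e_ij[:q1, :q1] = -inv_cov[i * q1:(i + 1) * q1, j * q1:(j + 1) * q1]
            w_ij = np.exp(e_ij)
            pdir = _two_site_direct(w_ij, fi[i], fi[j])
            indep = np.outer(fi[i], fi[j])
            mask = pdir > 0
            val = float((pdir[mask] * np.log(pdir[mask] / indep[mask])).sum())
            di[i, j] = di[j, i] = max(val, 0.0)
    return CoevolutionMatrix("DI", di)


# ---------------------------------------------------------------------------
# residue-level summaries
# ---------------------------------------------------------------------------

def _topk_mean(row: np.ndarray, k: int) -> float:
    """Mean of the k largest entries (all entries if fewer are available)."""
    if row.size == 0:
        return np.nan
    k = min(k, row.size)
    return float(np.sort(row)[-k:].mean())


def coevolution_summaries(matrix: CoevolutionMatrix) -> pd.DataFrame:
    """Row-wise summary statistics of a coevolution matrix.

    For residue i the off-diagonal row ``M[i, j != i]`` is reduced to the
    statistics in :data:`SUMMARY_NAMES`; ``mean_nbK`` averages the entries
    with sequence separation 1..K, and ``max_nb4`` is the maximum within
    separation 4.  Spans shorter than 5 fall back to the available pairs.
    """
    v = matrix.values
    length = len(matrix)
    rows = []
    for i in range(length):
        off = np.delete(v[i], i)
        nb = {k: [] for k in (1, 2, 3, 4)}
        for j in range(length):
            sep = abs(i - j)
            if 1 <= sep <= 4:
                for k in nb:
                    if sep <= k:
                        nb[k].append(v[i, j])
        rows.append(
            {
                "max": off.max() if off.size else np.nan,
                "top2mean": _topk_mean(off, 2),
                "top3mean": _topk_mean(off, 3),
                "top4mean": _topk_mean(off, 4),
                "top8mean": _topk_mean(off, 8),
                "mean": off.mean() if off.size else np.nan,
                "median": float(np.median(off)) if off.size else np.nan,
                "std": off.std() if off.size else np.nan,
                **{f"mean_nb{k}": float(np.mean(nb[k])) if nb[k] else np.nan for k in nb},
                "max_nb4": float(np.max(nb[4])) if nb[4] else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=list(SUMMARY_NAMES))


def normalise_per_tmd(values: np.ndarray) -> np.ndarray:
    """Min-max scale a per-residue feature to [0, 1] within one TMD.

    A constant input maps to all zeros, so the scaling is invariant under
    affine transforms of non-constant input.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 residues to normalise")
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi - lo <= 0 or not np.isfinite(hi - lo):
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def coevolution_features(aln: Alignment, params: DcaParams | None = None) -> pd.DataFrame:
    """The 52-column coevolution family: {MI, DI} x 13 summaries x {raw, norm}."""
    frames = {}
    for metric, fn in (("mi", mi_matrix), ("di", di_matrix)):
        summ = coevolution_summaries(fn(aln, params))
        for name in SUMMARY_NAMES:
            raw = summ[name].to_numpy()
            frames[f"{metric}_{name}"] = raw
            frames[f"{metric}_{name}_norm"] = normalise_per_tmd(np.nan_to_num(raw))
    return pd.DataFrame(frames)


def write_matrix_tsv(matrix: CoevolutionMatrix, path) -> None:
    """Long-format TSV (i, j, value) with 1-based indices, upper triangle."""
    length = len(matrix)
    rows = [
        (i + 1, j + 1, matrix.values[i, j])
        for i in range(length)
        for j in range(i + 1, length)
    ]
    pd.DataFrame(rows, columns=["i", "j", matrix.metric]).to_csv(path, sep="\t", index=False)
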
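"""Covariance-tensor comparison of a set of symmetric matrices.

Compares m symmetric n x n (co)variance or correlation matrices — here the
among-habitat fitness matrices of the parental, F1 and F4 generations —
simultaneously. Each matrix is vectorized with its off-diagonal elements
weighted by sqrt(2) (so Frobenius inner products are preserved), the
m-sample covariance of these vectors forms the S-matrix, and the
eigenvectors of S are refolded into unit-Frobenius-norm symmetric matrices,
the eigentensors E_k with eigenvalues alpha_k. A matrix's coordinate on E_k
is the Frobenius inner product <G, E_k>; projecting an eigenvector e of an
eigentensor through a matrix gives the quadratic form e' G e.

With draw-aligned posterior inputs the eigentensors are computed once, in a
fixed frame, from the posterior-mean S; coordinates, projections and alpha
are then evaluated per draw to carry posterior uncertainty. Per-draw
re-decomposition is available behind a flag for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .diagnostics import hpd_interval

log = logging.getLogger(__name__)


@dataclass
class MatrixSet:
    """m labelled symmetric matrices, optionally with aligned posterior draws.

    ``matrices`` has shape (m, n, n) for point estimates; ``draws`` (optional)
    has shape (m, n_draws, n, n) with draw index aligned across matrices.
    """

    labels: list[str]
    matrices: np.ndarray
    draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must have shape (m, n, n)")
        if len(self.labels) != self.matrices.shape[0]:
            raise ValueError("labels must match number of matrices")
        if not np.allclose(self.matrices, np.swapaxes(self.matrices, 1, 2), atol=1e-8):
            raise ValueError("matrices must be symmetric")
        if self.draws is not None:
            self.draws = np.asarray(self.draws, float)
            if self.draws.shape[0] != self.matrices.shape[0] or \
               self.draws.shape[2:] != self.matrices.shape[1:]:
                raise ValueError("draws must have shape (m, n_draws, n, n)")

    @classmethod
    def from_draws(cls, labels: list[str], draws: np.ndarray) -> "MatrixSet":
        draws = np.asarray(draws, float)
        return cls(labels, draws.mean(axis=1), draws)

    @property
    def n(self) -> int:
        return self.matrices.shape[1]

    @property
    def m(self) -> int:
        return self.matrices.shape[0]


@dataclass
class Eigentensor:
    alpha: float
    e_matrix: np.ndarray
    axis_values: np.ndarray       # eigenvalues lambda_i of E, descending |.|
    axis_vectors: np.ndarray      # columns e_i
    axis_proportions: np.ndarray  # lambda_i^2 / sum lambda_j^2


@dataclass
class TensorDecomposition:
    s: np.ndarray
    eigentensors: list[Eigentensor]
    labels: list[str] = field(default_factory=list)
    coordinates: np.ndarray | None = None        # (m, n_eigentensors)
    coordinate_draws: np.ndarray | None = None   # (m, n_draws, n_eigentensors)
    alpha_draws: np.ndarray | None = None        # (n_draws, n_eigentensors)

    @property
    def alphas(self) -> np.ndarray:
        return np.array([t.alpha for t in self.eigentensors])

    @property
    def alpha_proportions(self) -> np.ndarray:
        a = self.alphas
        return a / a.sum() if a.sum() > 0 else np.zeros_like(a)


def cov_to_corr(cov: np.ndarray) -> np.ndarray:
    """Scale a covariance matrix to a correlation matrix, r_ij = c_ij/sqrt(c_ii c_jj)."""
    cov = np.asarray(cov, float)
    dg = np.diag(cov)
    bad = np.flatnonzero(dg <= 0)
    if bad.size:
        raise ValueError(f"nonpositive variance for habitat index(es) {bad.tolist()}")
    s = 1.0 / np.sqrt(dg)
    r = cov * np.outer(s, s)
    np.fill_diagonal(r, 1.0)
    return r


def _vec_indices(n: int):
    """Row/col indices of the unique elements: diagonal first, then upper off-diagonals."""
    iu = np.triu_indices(n)
    diag = iu[0] == iu[1]
    order = np.argsort(~diag, kind="stable")  # diagonals first
    return iu[0][order], iu[1][order]


def vectorize(mat: np.ndarray) -> np.ndarray:
    """Stack unique elements with off-diagonals weighted by sqrt(2).

    Preserves the Frobenius inner product: vec(A) . vec(B) = <A, B>_F.
    Works on a single matrix or any leading batch shape.
    """
    mat = np.asarray(mat, float)
    n = mat.shape[-1]
    r, c = _vec_indices(n)
    w = np.where(r == c, 1.0, np.sqrt(2.0))
    return mat[..., r, c] * w


def unvectorize(v: np.ndarray, n: int) -> np.ndarray:
    """Refold a weighted vector into a symmetric matrix (off-diagonals / sqrt(2))."""
    r, c = _vec_indices(n)
    w = np.where(r == c, 1.0, np.sqrt(2.0))
    out = np.zeros(v.shape[:-1] + (n, n))
    out[..., r, c] = v / w
    out[..., c, r] = out[..., r, c]
    return out


def build_s_matrix(mats: MatrixSet | np.ndarray) -> np.ndarray:
    """Covariance (divisor m-1) among the vectorized matrices."""
    M = mats.matrices if isinstance(mats, MatrixSet) else np.asarray(mats, float)
    if M.shape[0] < 2:
        raise ValueError("need at least two matrices")
    V = vectorize(M)
    return np.cov(V, rowvar=False, ddof=1)


def _fix_sign(v: np.ndarray) -> np.ndarray:
    i = np.argmax(np.abs(v))
    return -v if v[i] < 0 else v


def decompose_s(s: np.ndarray, n: int, labels: list[str] | None = None) -> TensorDecomposition:
    """Eigen-decompose S and refold eigenvectors into eigentensors."""
    s = np.asarray(s, float)
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    alphas, vecs = np.linalg.eigh(s)
    order = np.argsort(alphas)[::-1]
    alphas, vecs = alphas[order], vecs[:, order]
    tensors = []
    for k in range(alphas.size):
        E = unvectorize(vecs[:, k], n)
        # orientation: positive trace when clearly signed (an eigentensor
        # describing a same-direction change in all elements), otherwise
        # largest-|element| positive
        tr = np.trace(E)
        if abs(tr) > 0.1:
            E = E if tr > 0 else -E
        else:
            E = unvectorize(_fix_sign(vecs[:, k]), n)
        av, avec = np.linalg.eigh(E)
        aorder = np.argsort(np.abs(av))[::-1]
        av, avec = av[aorder], avec[:, aorder]
        for j in range(avec.shape[1]):
            avec[:, j] = _fix_sign(avec[:, j])
        props = av ** 2 / (av ** 2).sum() if (av ** 2).sum() > 0 else np.zeros_like(av)
        tensors.append(Eigentensor(float(alphas[k]), E, av, avec, props))
    return TensorDecomposition(s, tensors, labels or [])


def matrix_coordinates(mats: MatrixSet, tensor: TensorDecomposition) -> TensorDecomposition:
    """Frobenius inner products <G_t, E_k> per matrix and eigentensor.

    When the MatrixSet carries aligned draws, per-draw coordinates are stored
    for HPD summaries; point coordinates use the point matrices.
    """
    E = np.stack([t.e_matrix for t in tensor.eigentensors])  # (K, n, n)
    tensor.labels = mats.labels
    tensor.coordinates = np.einsum("tij,kij->tk", mats.matrices, E)
    if mats.draws is not None:
        tensor.coordinate_draws = np.einsum("tdij,kij->tdk", mats.draws, E)
        Sd = per_draw_s(mats.draws)
        Ev = vectorize(E)  # (K, q)
        tensor.alpha_draws = np.einsum("kq,dqr,kr->dk", Ev, Sd, Ev)
    return tensor


def per_draw_s(draws: np.ndarray) -> np.ndarray:
    """S-matrix per aligned posterior draw; draws shape (m, n_draws, n, n)."""
    V = vectorize(np.swapaxes(draws, 0, 1))  # (n_draws, m, q)
    Vc = V - V.mean(axis=1, keepdims=True)
    return np.einsum("dmq,dmr->dqr", Vc, Vc) / (draws.shape[0] - 1)


def project_axis(axis: np.ndarray, mats: MatrixSet):
    """Quadratic form axis' G axis per matrix; (values, draw values or None)."""
    axis = np.asarray(axis, float)
    nrm = np.linalg.norm(axis)
    if not np.isclose(nrm, 1.0):
        log.warning("projection axis had norm %.6f; normalizing", nrm)
        axis = axis / nrm
    vals = np.einsum("i,tij,j->t", axis, mats.matrices, axis)
    dvals = None
    if mats.draws is not None:
        dvals = np.einsum("i,tdij,j->td", axis, mats.draws, axis)
    return vals, dvals


def tensor_analysis(mats: MatrixSet, n_eigentensors: int | None = None,
                    per_draw_frame: bool = False) -> TensorDecomposition:
    """Full tensor pipeline: S, eigentensors, coordinates (fixed-frame default).

    With ``per_draw_frame`` and draw-aligned input, S is re-decomposed for
    every draw and alpha draws come from each draw's own leading frame
    (labels of eigentensors are then not strictly comparable across draws).
    """
    if mats.m == 2:
        log.info("only two matrices: S has rank <= 1")
    if mats.draws is not None:
        S = per_draw_s(mats.draws).mean(axis=0)
    else:
        S = build_s_matrix(mats)
    dec = decompose_s(S, mats.n, mats.labels)
    dec = matrix_coordinates(mats, dec)
    if per_draw_frame and mats.draws is not None:
        Sd = per_draw_s(mats.draws)
        alphas = np.linalg.eigvalsh(Sd)[:, ::-1]
        dec.alpha_draws = alphas
    if n_eigentensors is not None:
        dec.eigentensors = dec.eigentensors[:n_eigentensors]
        if dec.coordinates is not None:
            dec.coordinates = dec.coordinates[:, :n_eigentensors]
        if dec.coordinate_draws is not None:
            dec.coordinate_draws = dec.coordinate_draws[:, :, :n_eigentensors]
    return dec


def summarize_coordinates(dec: TensorDecomposition, prob: float = 0.95) -> list[dict]:
    """Per-matrix, per-eigentensor coordinate summaries with HPD intervals."""
    rows = []
    K = len(dec.eigentensors)
    for t, lab in enumerate(dec.labels):
        for k in range(K):
            row = {"matrix": lab, "eigentensor": k + 1,
                   "coordinate": float(dec.coordinates[t, k])}
            if dec.coordinate_draws is not None:
                lo, hi = hpd_interval(dec.coordinate_draws[t, :, k], prob)
                row["hpd_low"], row["hpd_high"] = lo, hi
            rows.append(row)
    return rows
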
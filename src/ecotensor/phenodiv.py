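"""Multivariate phenotypic divergence among ecotypes and hybrids.

Implements the MANOVA-based divergence analysis: trait standardization,
the between/within sums-of-squares-and-cross-products (SSCP) partition,
Wilks' lambda tests with Bonferroni correction, the divergence matrix

    D = (MS_H - MS_E) / nf,

where MS_H and MS_E are the hypothesis and error mean-square matrices and
nf is the effective per-group sample size of an unbalanced one-way design,
and eigen-scores of individuals on the leading axes of D (d_max, d_2).

D estimates the among-group covariance of true multivariate group means
after removing within-group (residual) phenotypic variation, so its
eigenvectors span the directions of greatest mean-phenotype divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class StandardizationError(ValueError):
    """A trait column cannot be standardized (zero variance)."""


class RankDeficiencyError(np.linalg.LinAlgError):
    """The error SSCP matrix is singular; remove collinear traits."""


@dataclass
class TraitMatrix:
    """Individuals x traits with group and family labels.

    ``values`` holds one row per individual; ``group`` is the factor whose
    mean differences are under test (ecotype or hybrid generation label).
    """

    values: np.ndarray
    group: np.ndarray
    trait_names: list[str]
    family: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group = np.asarray(self.group)
        if self.values.ndim != 2:
            raise ValueError("trait values must be 2-D (individuals x traits)")
        if self.values.shape[0] != self.group.shape[0]:
            raise ValueError("group labels must match number of rows")
        if len(self.trait_names) != self.values.shape[1]:
            raise ValueError("trait_names must match number of columns")
        if np.isnan(self.values).any():
            raise ValueError("trait matrix contains missing values")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, trait_names: list[str],
                   group_col: str = "group", family_col: str | None = "family") -> "TraitMatrix":
        fam = df[family_col].to_numpy() if family_col and family_col in df else None
        return cls(df[trait_names].to_numpy(float), df[group_col].to_numpy(),
                   list(trait_names), fam)

    def subset(self, groups) -> "TraitMatrix":
        mask = np.isin(self.group, list(groups))
        fam = self.family[mask] if self.family is not None else None
        return TraitMatrix(self.values[mask], self.group[mask], self.trait_names, fam)


@dataclass
class SSCPDecomposition:
    sscp_h: np.ndarray
    sscp_e: np.ndarray
    df_h: int
    df_e: int
    group_sizes: dict = field(default_factory=dict)


@dataclass
class ManovaResult:
    wilks_lambda: float
    f_approx: float
    df1: float
    df2: float
    p_value: float
    alpha_corrected: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_corrected


@dataclass
class DivergenceMatrix:
    d: np.ndarray
    ms_h: np.ndarray
    ms_e: np.ndarray
    nf: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, descending eigenvalue order
    proportions: np.ndarray   # shares of the positive eigenvalues; NaN for negatives
    trait_names: list[str] = field(default_factory=list)


def standardize_traits(raw: TraitMatrix) -> TraitMatrix:
    """Center each trait to mean 0 and scale to sample standard deviation 1.

    Standardization is pooled over all rows passed in; pass the exact set of
    individuals (e.g. parentals + F4) whose shared scale the analysis needs.
    """
    mu = raw.values.mean(axis=0)
    sd = raw.values.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise StandardizationError(
            f"constant trait column(s): {[raw.trait_names[i] for i in bad]}"
        )
    return TraitMatrix((raw.values - mu) / sd, raw.group, raw.trait_names, raw.family)


def manova_sscp(traits: TraitMatrix) -> SSCPDecomposition:
    """One-way MANOVA partition of the total centered SSCP.

    sscp_h = sum_g n_g (xbar_g - xbar)(xbar_g - xbar)'  (df a-1)
    sscp_e = within-group centered cross-products       (df N-a)
    """
    X, g = traits.values, traits.group
    labels, inv = np.unique(g, return_inverse=True)
    a = labels.size
    if a < 2:
        raise ValueError("MANOVA needs at least two groups")
    N, p = X.shape
    if N - a < 1:
        raise ValueError("all groups are singletons: error df is zero")
    grand = X.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    sizes = {}
    for k, lab in enumerate(labels):
        Xg = X[inv == k]
        sizes[lab] = len(Xg)
        d = Xg.mean(axis=0) - grand
        H += len(Xg) * np.outer(d, d)
        C = Xg - Xg.mean(axis=0)
        E += C.T @ C
    return SSCPDecomposition(H, E, a - 1, N - a, sizes)


def wilks_test(decomp: SSCPDecomposition, n_tests: int = 1) -> ManovaResult:
    """Wilks' lambda with Rao's F approximation and Bonferroni-corrected alpha.

    lambda = det(E) / det(E + H); Rao's transformation gives an F statistic
    that is exact for df_h <= 2 or p <= 2 and an approximation otherwise.
    """
    E, H = decomp.sscp_e, decomp.sscp_h
    p = E.shape[0]
    sign, logdet_e = np.linalg.slogdet(E)
    if sign <= 0:
        raise RankDeficiencyError(
            "SSCP_E is singular; traits are collinear or df_e < p - remove traits"
        )
    _, logdet_t = np.linalg.slogdet(E + H)
    lam = float(np.exp(logdet_e - logdet_t))
    q = decomp.df_h
    v = decomp.df_e + q - (p + q + 1) / 2.0
    s2 = (p * p * q * q - 4.0) / (p * p + q * q - 5.0) if p * p + q * q - 5 > 0 else 1.0
    s = np.sqrt(s2) if s2 > 0 else 1.0
    df1 = p * q
    df2 = v * s - df1 / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    f = (1.0 - lam_s) / lam_s * df2 / df1 if lam_s > 0 else np.inf
    pval = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return ManovaResult(lam, float(f), float(df1), float(df2), pval, 0.05 / n_tests)


def effective_family_size(group_sizes) -> float:
    """Effective per-group n for an unbalanced one-way design.

    n0 = (N - sum(n_g^2)/N) / (a - 1); equals the common n when balanced.
    """
    n = np.asarray(list(group_sizes), dtype=float)
    if n.size < 2:
        raise ValueError("effective size needs at least two groups")
    if (n < 1).any():
        raise ValueError("group sizes must be >= 1")
    N = n.sum()
    return float((N - (n ** 2).sum() / N) / (n.size - 1))


def _fix_sign(vecs: np.ndarray) -> np.ndarray:
    """Make the largest-|loading| element of each column positive."""
    out = vecs.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def compute_d_matrix(decomp: SSCPDecomposition, nf: float,
                     trait_names: list[str] | None = None) -> DivergenceMatrix:
    """D = (MS_H - MS_E)/nf with its eigen-decomposition.

    Negative eigenvalues can occur (D is a difference of mean squares); they
    are retained but excluded from the divergence-proportion denominator so
    reported proportions lie in [0, 1].
    """
    if nf <= 0:
        raise ValueError("nf must be positive")
    ms_h = decomp.sscp_h / decomp.df_h
    ms_e = decomp.sscp_e / decomp.df_e
    d = (ms_h - ms_e) / nf
    d = (d + d.T) / 2.0
    vals, vecs = np.linalg.eigh(d)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], _fix_sign(vecs[:, order])
    pos = vals > 0
    props = np.full_like(vals, np.nan)
    if pos.any():
        props[pos] = vals[pos] / vals[pos].sum()
    return DivergenceMatrix(d, ms_h, ms_e, float(nf), vals, vecs, props,
                            trait_names or [])


def divergence_scores(dm: DivergenceMatrix, traits: TraitMatrix,
                      n_axes: int = 2) -> pd.DataFrame:
    """Project standardized individuals onto the leading axes of D.

    Returns one row per individual with its group label and scores on
    d_max, d_2, ... (axis_1, axis_2, ...).
    """
    if dm.trait_names and dm.trait_names != traits.trait_names:
        raise ValueError(
            f"trait names differ between D ({dm.trait_names}) and data ({traits.trait_names})"
        )
    scores = traits.values @ dm.eigenvectors[:, :n_axes]
    out = pd.DataFrame(scores, columns=[f"axis_{k+1}" for k in range(n_axes)])
    out.insert(0, "group", traits.group)
    return out


def pairwise_manovas(traits: TraitMatrix, focal: str, others: list[str],
                     n_tests: int | None = None) -> dict[str, ManovaResult]:
    """Separate two-group MANOVAs of ``focal`` against each of ``others``.

    The Bonferroni-corrected alpha uses the number of tests actually run
    unless ``n_tests`` overrides it.
    """
    nt = n_tests if n_tests is not None else len(others)
    results = {}
    for other in others:
        sub = traits.subset([focal, other])
        results[other] = wilks_test(manova_sscp(sub), n_tests=nt)
    return results
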
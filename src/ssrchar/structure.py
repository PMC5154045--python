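"""Model-free population-structure utilities for dominant band data.

Three pieces used downstream of Bayesian clustering and for DAPC-style
(discriminant analysis of principal components) exploration:

* ``evanno`` — the second-order rate-of-change statistic
  ``deltaK(K) = |L''(K)| / sd(lnP(K))`` over replicate log-likelihood runs
  of an external clustering program; peaks at the supported cluster number.
* ``pc_scores`` + ``kmeans_bic`` — K-means over principal-component scores
  of the 1/0 band matrix with BIC-based selection of the cluster number
  (``BIC(k) = n ln(W_k / n) + k ln(n)``, minimum = supported k).
* ``discriminant_project`` — Fisher discriminant axes maximizing
  between/within cluster scatter, for plotting cluster separation.

The Bayesian admixture MCMC itself is out of scope; this module consumes
its numeric log-likelihood output only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .bands import BandMatrix


# ---------------------------------------------------------------------------
# Evanno delta-K


@dataclass
class EvannoResult:
    """Per-K summary of replicate log-likelihoods and the deltaK statistic.

    ``table`` columns: mean_lnp, sd_lnp, lprime (first difference of
    mean_lnp), ldoubleprime (second difference) and delta_k, indexed by K.
    deltaK is defined only for interior K with sd > 0; ``best_k`` is the
    argmax of deltaK over the defined values (None if none is defined or
    the curve is flat at zero).
    """

    table: pd.DataFrame
    best_k: int | None


def read_run_log_table(path_or_buffer) -> pd.DataFrame:
    """Read a TSV of clustering runs with columns K, replicate, lnP."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    required = {"K", "replicate", "lnP"}
    if not required <= set(df.columns):
        raise ValueError(f"run table needs columns {sorted(required)}")
    return df


def evanno(table: pd.DataFrame) -> EvannoResult:
    """Compute the deltaK statistic from a (K, replicate, lnP) table.

    Requires a contiguous K range of length >= 3 with >= 2 replicates per
    K.  ``deltaK(K) = |mean_lnP(K+1) - 2 mean_lnP(K) + mean_lnP(K-1)| /
    sd_lnP(K)``; K values where the replicate sd is 0 are flagged
    undefined (NaN) and excluded from the argmax.  Adding a constant to
    every lnP leaves deltaK unchanged, and replicate order is irrelevant.
    """
    df = pd.DataFrame(table)[["K", "replicate", "lnP"]].copy()
    grouped = df.groupby("K")["lnP"]
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    counts = grouped.size()
    ks = mean.index.to_numpy()
    if len(ks) < 3:
        raise ValueError("Evanno needs a K range of length >= 3")
    if not np.array_equal(ks, np.arange(ks.min(), ks.max() + 1)):
        raise ValueError("K values must form a contiguous ascending range")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 replicates per K; too few at K={bad}")

    lprime = mean.diff()  # L'(K) = mean(K) - mean(K-1)
    ldouble = lprime.shift(-1) - lprime  # L''(K) = L'(K+1) - L'(K)
    delta = ldouble.abs() / sd
    delta[sd == 0] = np.nan
    # deltaK is an interior-K statistic
    delta.iloc[0] = np.nan
    delta.iloc[-1] = np.nan

    out = pd.DataFrame(
        {
            "mean_lnp": mean,
            "sd_lnp": sd,
            "lprime": lprime,
            "ldoubleprime": ldouble,
            "delta_k": delta,
        }
    )
    defined = delta.dropna()
    best_k = None
    if not defined.empty and defined.max() > 0:
        best_k = int(defined.idxmax())
    return EvannoResult(table=out, best_k=best_k)


# ---------------------------------------------------------------------------
# Principal-coordinate scores of the band matrix


def encode_numeric(matrix: BandMatrix, impute: bool = True) -> pd.DataFrame:
    """1/0 numeric encoding of the band matrix, failed cells imputed.

    Failed (NA) cells are replaced by the band's panel mean so every
    genotype stays usable; with ``impute=False`` genotypes with any failure
    are dropped instead.
    """
    data = matrix.scores.copy()
    if impute:
        data = data.fillna(data.mean(axis=0))
        # a band never scored anywhere stays NaN; drop it
        data = data.dropna(axis=1, how="all")
    else:
        data = data.dropna(axis=0, how="any")
    return data


@dataclass
class PcScores:
    scores: pd.DataFrame  # genotypes x components
    variance_fraction: np.ndarray

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_fraction)


def pc_scores(
    matrix: BandMatrix | pd.DataFrame, n_pcs: int | None = None, impute: bool = True
) -> PcScores:
    """Centered principal-component scores of the encoded band matrix.

    Returns the genotype x component coordinates and per-component variance
    fractions (so a "retain components explaining X% of variation" rule can
    be applied).  With all components kept, the scores preserve the
    pairwise Euclidean distances of the centered data.
    """
    data = encode_numeric(matrix) if isinstance(matrix, BandMatrix) else matrix
    values = np.asarray(data, dtype=float)
    if np.allclose(values.std(axis=0), 0):
        raise ValueError("constant matrix has no principal components")
    max_rank = min(values.shape[0] - 1, values.shape[1])
    k = max_rank if n_pcs is None else int(n_pcs)
    if not 1 <= k <= max_rank:
        raise ValueError(f"n_pcs must be in [1, {max_rank}]")
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(values)
    scores = pd.DataFrame(
        coords,
        index=data.index,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return PcScores(scores=scores, variance_fraction=pca.explained_variance_ratio_)


def n_pcs_for_variance(pcs: PcScores, fraction: float) -> int:
    """Smallest component count whose cumulative variance reaches ``fraction``."""
    cum = pcs.cumulative_variance
    idx = np.searchsorted(cum, fraction - 1e-12)
    return int(min(idx + 1, len(cum)))


# ---------------------------------------------------------------------------
# K-means with BIC selection


@dataclass
class ClusterSolution:
    k: int
    assignments: np.ndarray
    wss: float  # within-cluster sum of squares (best of restarts)
    bic: float


@dataclass
class KmeansBicResult:
    solutions: list[ClusterSolution]
    selected_k: int  # unconstrained argmin of BIC
    selected_k_ge2: int  # argmin over k >= 2

    def solution(self, k: int) -> ClusterSolution:
        return self.solutions[k - 1]

    def bic_curve(self) -> pd.Series:
        return pd.Series({s.k: s.bic for s in self.solutions}, name="bic")


def kmeans_bic(
    scores: pd.DataFrame | np.ndarray,
    k_max: int,
    restarts: int = 20,
    seed: int = 0,
) -> KmeansBicResult:
    """Successive K-means with BIC-based selection of the cluster number.

    For k = 1..k_max runs k-means++ with ``restarts`` restarts, keeps the
    best within-cluster sum of squares W_k, and scores
    ``BIC(k) = n ln(W_k / n) + k ln(n)``.  The supported cluster number
    minimizes BIC (ties broken toward smaller k); because the smallest
    admissible k in typical software is 2, the argmin over k >= 2 is
    reported alongside the unconstrained one.  Deterministic given ``seed``.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds the {n} genotypes")
    solutions = []
    for k in range(1, k_max + 1):
        if k == 1:
            centroid = X.mean(axis=0)
            labels = np.zeros(n, dtype=int)
            wss = float(((X - centroid) ** 2).sum())
        else:
            km = KMeans(
                n_clusters=k,
                n_init=restarts,
                init="k-means++",
                random_state=seed,
            ).fit(X)
            labels = km.labels_.astype(int)
            wss = float(km.inertia_)
        # W can be 0 on degenerate data (duplicated points); floor for the log
        bic = n * np.log(max(wss, 1e-12) / n) + k * np.log(n)
        solutions.append(ClusterSolution(k=k, assignments=labels, wss=wss, bic=float(bic)))
    bics = np.array([s.bic for s in solutions])
    selected = int(np.argmin(bics)) + 1
    selected_ge2 = int(np.argmin(bics[1:])) + 2
    return KmeansBicResult(
        solutions=solutions, selected_k=selected, selected_k_ge2=selected_ge2
    )


# ---------------------------------------------------------------------------
# Fisher discriminant projection


def discriminant_project(
    scores: pd.DataFrame | np.ndarray,
    assignments: Sequence[int],
) -> pd.DataFrame:
    """Project genotypes onto Fisher discriminant axes of their clusters.

    Solves the generalized eigenproblem ``S_b v = lambda S_w v`` for the
    between-cluster (S_b) and within-cluster (S_w) scatter of the retained
    components, keeping the top (k - 1) axes.  Axis signs are canonicalized
    so the first nonzero loading of each axis is positive.  If S_w is
    singular, retain fewer principal components before projecting.
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(assignments)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("scores and assignments must align")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 clusters for a discriminant projection")
    sizes = np.array([(labels == c).sum() for c in classes])
    if (sizes < 2).any():
        raise ValueError("every cluster needs >= 2 members")
    grand = X.mean(axis=0)
    p = X.shape[1]
    sw = np.zeros((p, p))
    sb = np.zeros((p, p))
    for c, nc in zip(classes, sizes):
        block = X[labels == c]
        mu = block.mean(axis=0)
        centered = block - mu
        sw += centered.T @ centered
        diff = (mu - grand)[:, None]
        sb += nc * (diff @ diff.T)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(sb, sw)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "within-cluster scatter is singular; reduce the number of "
            "retained principal components and try again"
        ) from exc
    order = np.argsort(eigvals)[::-1][: len(classes) - 1]
    axes = eigvecs[:, order]
    # canonical sign: first nonzero loading positive
    for j in range(axes.shape[1]):
        col = axes[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            axes[:, j] = -col
    projected = X @ axes
    index = scores.index if isinstance(scores, pd.DataFrame) else pd.RangeIndex(len(X))
    return pd.DataFrame(
        projected, index=index, columns=[f"LD{i + 1}" for i in range(axes.shape[1])]
    )
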
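"""Exploratory genetic structure: DAPC and spatial PCA.

DAPC (discriminant analysis of principal components) first transforms allele
dosages with PCA, picks the number of clusters by running k-means across a k
range and minimizing ``BIC(k) = n ln(WSS_k / n) + k ln(n)``, then fits a
linear discriminant analysis on a reduced number of PCs chosen with the
a-score (observed reassignment rate minus its permutation expectation, which
penalizes overfitting).

sPCA (spatial PCA) eigen-decomposes ``(1/n) X' H X`` where X is the centred
dosage matrix and H the symmetrized row-normalized spatial weight matrix of a
connection network: each eigenvalue is exactly var(score) x Moran's I(score),
so large positive eigenvalues capture global (cline/patch) structure and
large negative ones local (neighbour-contrast) structure. Significance comes
from permuting genotype rows against locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, distance_matrix
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .types import MISSING, GenotypeMatrix, PopulationMap, ValidationError


# ---------------------------------------------------------------------------
# Allele dosage matrix
# ---------------------------------------------------------------------------

def allele_dosage_matrix(
    g: GenotypeMatrix, center: bool = True, scale: bool = False
) -> pd.DataFrame:
    """Individuals x alleles dosage matrix (0/1/2 copies).

    Missing calls are imputed with the allele's mean dosage (the standard
    default before PCA on codominant markers); columns are (locus, allele)
    pairs. Centring subtracts the column mean; scaling divides by the column
    standard deviation where it is non-zero.
    """
    cols: list[tuple[str, int]] = []
    blocks: list[np.ndarray] = []
    for j, loc in enumerate(g.locus_names):
        calls = g.calls[:, j, :]
        present = calls[:, 0] != MISSING
        alleles = np.unique(calls[present].ravel())
        block = np.zeros((g.n_individuals, len(alleles)))
        for a_i, a in enumerate(alleles):
            block[:, a_i] = (calls == a).sum(axis=1)
        block[~present] = np.nan
        cols.extend((loc, int(a)) for a in alleles)
        blocks.append(block)
    X = np.concatenate(blocks, axis=1) if blocks else np.zeros((g.n_individuals, 0))
    col_mean = np.nanmean(X, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(X))
    X[nan_rows, nan_cols] = col_mean[nan_cols]
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    return pd.DataFrame(
        X, index=list(g.individual_ids),
        columns=pd.MultiIndex.from_tuples(cols, names=["locus", "allele"]),
    )


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

class DAPC(BaseEstimator):
    """Discriminant analysis of principal components.

    Parameters
    ----------
    k_range : iterable of cluster numbers to score (default 1..10).
    criterion : how to pick the best k from the BIC curve. ``"diffNgroup"``
        (default, mirroring the reference implementation of the method)
        clusters the successive BIC differences into a sharp-drop group and a
        plateau group (Ward linkage) and keeps the last k of the sharp-drop
        group — robust to the long flat tail the k ln(n) penalty leaves on
        discrete dosage data, where the raw argmin tends to over-split.
        ``"min"`` is the plain BIC argmin.
    n_pca_grid : candidate PC counts for the a-score optimisation
        (default: 1..min(20, available PCs)).
    n_discriminant : discriminant axes to keep (default k-1).
    a_score_permutations : label permutations per a-score evaluation.
    seed : RNG seed for k-means and the a-score permutations.

    Attributes (after ``fit``)
    --------------------------
    bic_ : pd.Series of BIC per k; ``best_k_`` its argmin.
    labels_ : cluster assignment per individual.
    n_pca_ : retained PC count; ``a_scores_`` the score per candidate.
    scores_ : individuals x discriminant-axis coordinates.
    """

    def __init__(
        self,
        k_range=range(1, 11),
        criterion: str = "diffNgroup",
        n_pca_grid=None,
        n_discriminant: int | None = None,
        a_score_permutations: int = 10,
        seed: int = 0,
    ):
        self.k_range = k_range
        self.criterion = criterion
        self.n_pca_grid = n_pca_grid
        self.n_discriminant = n_discriminant
        self.a_score_permutations = a_score_permutations
        self.seed = seed

    @staticmethod
    def _select_k(bic: pd.Series, criterion: str) -> int:
        if criterion == "min" or len(bic) < 3:
            return int(bic.idxmin())
        if criterion != "diffNgroup":
            raise ValidationError(f"unknown criterion {criterion!r}")
        from scipy.cluster.hierarchy import fcluster, linkage

        ks = list(bic.index)
        d = np.diff(bic.to_numpy())
        grp = fcluster(linkage(d.reshape(-1, 1), method="ward"), 2, "maxclust")
        means = {g: d[grp == g].mean() for g in set(grp)}
        sharp = min(means, key=means.get)
        if means[sharp] >= 0:  # BIC never drops: no structure
            return ks[0]
        return ks[int(np.max(np.nonzero(grp == sharp)[0])) + 1]

    def fit(self, g: GenotypeMatrix, m: PopulationMap | None = None) -> "DAPC":
        ks = sorted(set(int(k) for k in self.k_range))
        X = allele_dosage_matrix(g).to_numpy()
        n = X.shape[0]
        if n < 2 * max(ks):
            raise ValidationError(
                f"need >= {2 * max(ks)} individuals for k_range up to {max(ks)}"
            )
        if max(ks) > n - 1:
            raise ValidationError("k_range exceeds n - 1")
        pca = PCA(n_components=min(n - 1, X.shape[1]), random_state=self.seed)
        pcs = pca.fit_transform(X)
        self.pca_ = pca

        bic = {}
        labels_by_k = {}
        for k in ks:
            if k == 1:
                wss = float(((pcs - pcs.mean(axis=0)) ** 2).sum())
                labels_by_k[k] = np.zeros(n, dtype=int)
            else:
                km = KMeans(n_clusters=k, n_init=10, random_state=self.seed).fit(pcs)
                wss = float(km.inertia_)
                labels_by_k[k] = km.labels_
            bic[k] = n * np.log(wss / n) + k * np.log(n)
        self.bic_ = pd.Series(bic, name="bic")
        self.best_k_ = self._select_k(self.bic_, self.criterion)
        self.labels_ = labels_by_k[self.best_k_]

        if self.best_k_ == 1:
            self.n_pca_ = 0
            self.a_scores_ = pd.Series(dtype=float)
            self.scores_ = pd.DataFrame(index=list(g.individual_ids))
            return self

        grid = self.n_pca_grid
        if grid is None:
            grid = range(1, min(20, pcs.shape[1]) + 1)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xDA]))
        a_scores = {}
        for npca in grid:
            a_scores[npca] = self._a_score(pcs[:, :npca], self.labels_, rng)
        self.a_scores_ = pd.Series(a_scores, name="a_score")
        self.n_pca_ = int(self.a_scores_.idxmax())

        n_da = self.n_discriminant or (self.best_k_ - 1)
        lda = LinearDiscriminantAnalysis(n_components=min(n_da, self.best_k_ - 1))
        scores = lda.fit_transform(pcs[:, : self.n_pca_], self.labels_)
        self.lda_ = lda
        self.scores_ = pd.DataFrame(
            scores, index=list(g.individual_ids),
            columns=[f"ld{i + 1}" for i in range(scores.shape[1])],
        )
        self.assignment_accuracy_ = float(
            (lda.predict(pcs[:, : self.n_pca_]) == self.labels_).mean()
        )
        return self

    def _a_score(self, pcs: np.ndarray, labels: np.ndarray,
                 rng: np.random.Generator) -> float:
        lda = LinearDiscriminantAnalysis()
        obs = float((lda.fit(pcs, labels).predict(pcs) == labels).mean())
        exp = []
        for _ in range(self.a_score_permutations):
            perm = rng.permutation(labels)
            lda_p = LinearDiscriminantAnalysis()
            exp.append(float((lda_p.fit(pcs, perm).predict(pcs) == perm).mean()))
        return obs - float(np.mean(exp))

    def predict(self, g: GenotypeMatrix) -> np.ndarray:
        pcs = self.pca_.transform(allele_dosage_matrix(g).to_numpy())
        return self.lda_.predict(pcs[:, : self.n_pca_])


def dapc(g, m=None, k_range=range(1, 11), seed: int = 0) -> DAPC:
    return DAPC(k_range=k_range, seed=seed).fit(g, m)


# ---------------------------------------------------------------------------
# Connection networks and spatial weights
# ---------------------------------------------------------------------------

def _gabriel_edges(pts: np.ndarray) -> set[tuple[int, int]]:
    """Gabriel graph edges: (i, j) kept iff the open disc on segment ij
    contains no other point. Candidate edges come from the Delaunay
    triangulation (the Gabriel graph is one of its subgraphs)."""
    from scipy.spatial import QhullError

    cand = set()
    try:
        tri = Delaunay(pts)
        for simplex in tri.simplices:
            for a in range(len(simplex)):
                for b in range(a + 1, len(simplex)):
                    i, j = sorted((simplex[a], simplex[b]))
                    cand.add((int(i), int(j)))
    except QhullError:  # degenerate (e.g. collinear) input: test all pairs
        n = len(pts)
        cand = {(i, j) for i in range(n) for j in range(i + 1, n)}
    edges = set()
    for i, j in cand:
        mid = (pts[i] + pts[j]) / 2
        r2 = ((pts[i] - pts[j]) ** 2).sum() / 4
        d2 = ((pts - mid) ** 2).sum(axis=1)
        d2[[i, j]] = np.inf
        if (d2 > r2 - 1e-12).all():
            edges.add((i, j))
    return edges


def spatial_weights(pts: np.ndarray, network: str = "knn", k: int = 5,
                    d_max: float | None = None) -> np.ndarray:
    """Row-normalized spatial weight matrix from a connection network.

    ``network`` is one of ``"knn"`` (symmetrized k-nearest neighbours),
    ``"gabriel"`` or ``"distance"`` (all pairs within ``d_max``). Raises if
    the network is disconnected.
    """
    n = len(pts)
    W = np.zeros((n, n))
    if network == "knn":
        dm = distance_matrix(pts, pts)
        np.fill_diagonal(dm, np.inf)
        nb = np.argsort(dm, axis=1)[:, :k]
        for i in range(n):
            W[i, nb[i]] = 1.0
        W = np.maximum(W, W.T)
    elif network == "gabriel":
        for i, j in _gabriel_edges(pts):
            W[i, j] = W[j, i] = 1.0
    elif network == "distance":
        if d_max is None:
            raise ValidationError("distance network needs d_max")
        dm = distance_matrix(pts, pts)
        W = ((dm > 0) & (dm <= d_max)).astype(float)
    else:
        raise ValidationError(f"unknown network {network!r}")
    n_comp, _ = connected_components(W > 0, directed=False)
    if n_comp > 1:
        raise ValidationError(
            f"connection network has {n_comp} components; increase k or d_max"
        )
    rs = W.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return W / rs


# ---------------------------------------------------------------------------
# sPCA
# ---------------------------------------------------------------------------

class SPCA(BaseEstimator):
    """Spatial principal component analysis of allele dosages.

    Individual coordinates are the population coordinates plus Gaussian
    jitter (sd ``jitter_sd`` degrees) so co-located individuals get distinct
    positions for the connection network.

    Attributes (after ``fit``)
    --------------------------
    eigenvalues_ : sorted descending; positive = global, negative = local.
    scores_ : individuals x axes (axes ordered like the eigenvalues).
    axis_variance_, axis_moran_ : per-axis var(score) and Moran's I, whose
        product reproduces the eigenvalue.
    """

    def __init__(self, network: str = "knn", k: int = 5, d_max: float | None = None,
                 jitter_sd: float = 0.2, seed: int = 0):
        self.network = network
        self.k = k
        self.d_max = d_max
        self.jitter_sd = jitter_sd
        self.seed = seed

    def _coords(self, g: GenotypeMatrix, m: PopulationMap) -> np.ndarray:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x5bca]))
        pts = np.array(
            [m.coords[m.assignment[i]] for i in g.individual_ids], dtype=float
        )
        return pts + rng.normal(0.0, self.jitter_sd, size=pts.shape)

    def fit(self, g: GenotypeMatrix, m: PopulationMap) -> "SPCA":
        X = allele_dosage_matrix(g).to_numpy()
        pts = self._coords(g, m)
        L = spatial_weights(pts, self.network, self.k, self.d_max)
        H = (L + L.T) / 2.0
        n = X.shape[0]
        C = X.T @ H @ X / n
        eigval, eigvec = np.linalg.eigh(C)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        scores = X @ eigvec
        var = (scores**2).sum(axis=0) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            moran = np.einsum("ia,ij,ja->a", scores, H, scores) / (scores**2).sum(axis=0)
        self.X_ = X
        self.H_ = H
        self.coords_ = pts
        self.eigenvalues_ = eigval
        self.components_ = eigvec
        self.scores_ = pd.DataFrame(
            scores, index=list(g.individual_ids),
            columns=[f"axis{i + 1}" for i in range(scores.shape[1])],
        )
        self.axis_variance_ = var
        self.axis_moran_ = moran
        return self

    def global_local_tests(self, n_perm: int = 10_000, seed: int | None = None):
        """Monte-Carlo tests of global and local spatial structure.

        Statistic: the largest positive eigenvalue (global) and the largest
        eigenvalue magnitude on the negative side (local) of the spatially
        weighted covariance; the null permutes genotype rows against
        locations. Add-one p-values.
        """
        seed = self.seed if seed is None else seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x61]))
        obs_global = float(self.eigenvalues_.max())
        obs_local = float(-self.eigenvalues_.min())
        n = self.X_.shape[0]
        hits_g = hits_l = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Xp = self.X_[perm]
            Cp = Xp.T @ self.H_ @ Xp / n
            ev = np.linalg.eigvalsh(Cp)
            hits_g += ev[-1] >= obs_global - 1e-12
            hits_l += -ev[0] >= obs_local - 1e-12
        return (
            (1 + hits_g) / (1 + n_perm),
            (1 + hits_l) / (1 + n_perm),
        )


def spca(g, m, network: str = "knn", k: int = 5, d_max: float | None = None,
         jitter_sd: float = 0.2, seed: int = 0) -> SPCA:
    return SPCA(network, k, d_max, jitter_sd, seed).fit(g, m)
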
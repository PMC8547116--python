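"""Matrix-correlation inference: Mantel tests and multiple matrix regression.

Both tests operate on the lower-triangle vectors of labelled pairwise
matrices. Significance comes from joint row/column permutations of the
response matrix (the only exchangeable unit in distance-matrix regression),
with add-one p-values so a permutation p is never exactly zero.

:class:`MantelTest` and :class:`MMRR` are scikit-learn-style estimators
(``fit`` + trailing-underscore attributes); :func:`mantel_test` and
:func:`mmrr` are thin functional wrappers returning frozen result records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .differentiation import FstMatrix, linearize_fst
from .types import PairwiseMatrix, ValidationError


def _check_aligned(mats: Sequence[PairwiseMatrix]) -> list[str]:
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            if set(m.labels) == set(labels):
                raise ValidationError(
                    "matrices share labels but in different order; reorder first"
                )
            raise ValidationError("matrices have different labels")
    return list(labels)


def _tri_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(n, k=-1)


def _permuted_tris(
    values: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Lower triangles of ``values`` under ``n_perm`` joint row/col permutations."""
    n = values.shape[0]
    i, j = _tri_indices(n)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    return values[perms[:, i], perms[:, j]]


# ---------------------------------------------------------------------------
# Climate dissimilarity
# ---------------------------------------------------------------------------

def climate_dissimilarity(values: Mapping[str, float] | pd.Series) -> PairwiseMatrix:
    """Absolute-difference dissimilarity matrix from one value per population."""
    if isinstance(values, pd.Series):
        values = values.to_dict()
    labels = list(values)
    v = np.array([values[p] for p in labels], dtype=float)
    return PairwiseMatrix(labels, np.abs(v[:, None] - v[None, :]))


def extract_climate_values(raster, coords: Mapping[str, tuple[float, float]]) -> pd.Series:
    """Climate raster value at each population's cell."""
    out = {}
    for p, (lon, lat) in coords.items():
        val = raster.value_at(lon, lat)
        if val == raster.nodata_value:
            raise ValidationError(f"population {p!r} falls on a nodata climate cell")
        out[p] = val
    return pd.Series(out, name="climate")


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    tail: str
    seed: int


class MantelTest(BaseEstimator):
    """Mantel correlation between two distance matrices.

    The statistic is the Pearson correlation of the lower-triangle vectors;
    the null is built by jointly permuting the rows and columns of Y.

    Parameters
    ----------
    n_permutations : permutations for the null (default 10 000).
    tail : "upper", "lower" or "two-sided".
    seed : RNG seed, recorded in the result.
    """

    def __init__(self, n_permutations: int = 10_000, tail: str = "upper", seed: int = 0):
        self.n_permutations = n_permutations
        self.tail = tail
        self.seed = seed

    def fit(self, X: PairwiseMatrix, Y: PairwiseMatrix) -> "MantelTest":
        _check_aligned([X, Y])
        if X.n < 4:
            raise ValidationError("Mantel test needs at least 4 populations")
        x, y = X.tri(), Y.tri()
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValidationError("zero-variance distance triangle")
        r_obs = float(np.corrcoef(x, y)[0, 1])
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x3A]))
        ytris = _permuted_tris(Y.values, self.n_permutations, rng)
        yc = ytris - ytris.mean(axis=1, keepdims=True)
        xc = x - x.mean()
        denom = np.sqrt((yc**2).sum(axis=1)) * np.sqrt((xc**2).sum())
        r_perm = (yc @ xc) / denom
        if self.tail == "upper":
            hits = int(np.sum(r_perm >= r_obs - 1e-12))
        elif self.tail == "lower":
            hits = int(np.sum(r_perm <= r_obs + 1e-12))
        elif self.tail == "two-sided":
            hits = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
        else:
            raise ValidationError(f"unknown tail {self.tail!r}")
        self.r_ = r_obs
        self.p_value_ = (1 + hits) / (1 + self.n_permutations)
        self.result_ = MantelResult(
            r_obs, self.p_value_, self.n_permutations, self.tail, self.seed
        )
        return self


def mantel_test(
    X: PairwiseMatrix, Y: PairwiseMatrix,
    n_perm: int = 10_000, tail: str = "upper", seed: int = 0,
) -> MantelResult:
    return MantelTest(n_perm, tail, seed).fit(X, Y).result_


# ---------------------------------------------------------------------------
# MMRR
# ---------------------------------------------------------------------------

@dataclass
class MMRRResult:
    predictors: list[str]
    coefficients: np.ndarray  # intercept first
    t_statistics: np.ndarray  # predictors only
    p_values: np.ndarray  # predictors only, permutation two-sided on |t|
    r_squared: float
    f_statistic: float
    f_p_value: float
    n_permutations: int
    seed: int

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[1 + self.predictors.index(name)])

    def p_value(self, name: str) -> float:
        return float(self.p_values[self.predictors.index(name)])


class MMRR(BaseEstimator):
    """Multiple regression on distance matrices with randomization.

    OLS of the response triangle on predictor triangles (intercept included);
    per-coefficient and overall-F significance from jointly permuting the
    rows/columns of the response matrix and recomputing t and F each time
    (two-sided on |t|).

    Parameters
    ----------
    n_permutations : permutations for the null (default 10 000).
    seed : RNG seed, recorded in the result.
    """

    def __init__(self, n_permutations: int = 10_000, seed: int = 0):
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(
        self,
        X: Sequence[PairwiseMatrix],
        y: PairwiseMatrix,
        names: Sequence[str] | None = None,
    ) -> "MMRR":
        X = list(X)
        if names is None:
            names = [f"x{i + 1}" for i in range(len(X))]
        _check_aligned([y, *X])
        tris = np.column_stack([m.tri() for m in X])
        ytri = y.tri()
        n_pairs, p = tris.shape
        if n_pairs < p + 2:
            raise ValidationError("fewer pairs than predictors + intercept + 1")
        if p > 1:
            cc = np.corrcoef(tris, rowvar=False)
            ii, jj = np.triu_indices(p, k=1)
            worst = np.argmax(np.abs(cc[ii, jj]))
            if np.abs(cc[ii, jj][worst]) > 0.999:
                raise ValidationError(
                    f"collinear predictors: {names[ii[worst]]!r} and {names[jj[worst]]!r}"
                )
        design = np.column_stack([np.ones(n_pairs), tris])
        xtx_inv = np.linalg.inv(design.T @ design)
        hat = xtx_inv @ design.T
        dof = n_pairs - p - 1

        def t_and_f(yv: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
            beta = yv @ hat.T  # (..., p+1)
            resid = yv - beta @ design.T
            rss = (resid**2).sum(axis=-1)
            tss = ((yv - yv.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
            sigma2 = rss / dof
            se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)).reshape(beta.shape))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = beta / se
                f = ((tss - rss) / p) / (rss / dof)
            return beta, t, f, 1.0 - rss / tss

        beta, t_obs, f_obs, r2 = t_and_f(ytri[None, :])
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x33B]))
        ytris = _permuted_tris(y.values, self.n_permutations, rng)
        _, t_perm, f_perm, _ = t_and_f(ytris)
        t_pred_obs = np.abs(t_obs[0, 1:])
        hits = (np.abs(t_perm[:, 1:]) >= t_pred_obs[None, :] - 1e-12).sum(axis=0)
        p_vals = (1 + hits) / (1 + self.n_permutations)
        f_hits = int(np.sum(f_perm >= f_obs[0] - 1e-12))

        self.predictor_names_ = list(names)
        self.intercept_ = float(beta[0, 0])
        self.coef_ = beta[0, 1:].copy()
        self.t_statistics_ = t_obs[0, 1:].copy()
        self.p_values_ = p_vals
        self.r_squared_ = float(r2[0])
        self.f_statistic_ = float(f_obs[0])
        self.f_p_value_ = (1 + f_hits) / (1 + self.n_permutations)
        self.result_ = MMRRResult(
            list(names), beta[0].copy(), self.t_statistics_, p_vals,
            self.r_squared_, self.f_statistic_, self.f_p_value_,
            self.n_permutations, self.seed,
        )
        return self

    def predict(self, X: Sequence[PairwiseMatrix]) -> np.ndarray:
        tris = np.column_stack([m.tri() for m in X])
        return self.intercept_ + tris @ self.coef_


def mmrr(
    Y: PairwiseMatrix,
    X: Sequence[PairwiseMatrix],
    n_perm: int = 10_000,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> MMRRResult:
    return MMRR(n_perm, seed).fit(X, Y, names=names).result_


# ---------------------------------------------------------------------------
# IBD / IBE suite
# ---------------------------------------------------------------------------

def ibd_ibe_suite(
    fst: FstMatrix | PairwiseMatrix,
    geo: PairwiseMatrix,
    resist: Mapping[str, PairwiseMatrix] | None = None,
    clim: Mapping[str, PairwiseMatrix] | None = None,
    wind: PairwiseMatrix | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    log_geo_mantel: bool = True,
    log_geo_mmrr: bool = False,
    joint_climate: bool = False,
) -> pd.DataFrame:
    """Run the full isolation-by-distance / -resistance / -environment battery.

    With linearized FST as the response: (a) Mantel against (log) geographic
    distance; (b) single-predictor MMRR per resistance model; (c) MMRR per
    climate variable with geographic distance as covariate; (d) MMRR with the
    wind cost matrix. Returns one tidy row per test.
    """
    y = linearize_fst(fst)
    labels = y.labels
    geo = geo if geo.labels == labels else geo.reorder(labels)
    rows = []

    def log_mat(mat: PairwiseMatrix) -> PairwiseMatrix:
        v = mat.values.copy()
        off = ~np.eye(mat.n, dtype=bool)
        if (v[off] <= 0).any():
            raise ValidationError("non-positive off-diagonal distance; cannot log")
        v[off] = np.log(v[off])
        return PairwiseMatrix(labels, v)

    mres = mantel_test(log_mat(geo) if log_geo_mantel else geo, y,
                       n_perm=n_perm, seed=seed)
    rows.append({
        "test": "ibd_mantel", "predictor": "log_geographic" if log_geo_mantel else "geographic",
        "statistic": mres.r, "r_squared": mres.r**2, "beta": np.nan,
        "p_value": mres.p_value, "n_perm": n_perm, "seed": seed,
    })

    geo_mmrr = log_mat(geo) if log_geo_mmrr else geo

    for model, mat in (resist or {}).items():
        mat = mat if mat.labels == labels else mat.reorder(labels)
        res = mmrr(y, [mat], n_perm=n_perm, seed=seed, names=[model])
        rows.append({
            "test": f"ibr_{model}", "predictor": model,
            "statistic": res.t_statistics[0], "r_squared": res.r_squared,
            "beta": res.coefficients[1], "p_value": res.p_values[0],
            "n_perm": n_perm, "seed": seed,
        })

    clim = clim or {}
    if joint_climate and clim:
        mats = [m if m.labels == labels else m.reorder(labels) for m in clim.values()]
        res = mmrr(y, [*mats, geo_mmrr], n_perm=n_perm, seed=seed,
                   names=[*clim.keys(), "geographic"])
        for i, var in enumerate(clim.keys()):
            rows.append({
                "test": "ibe_joint", "predictor": var,
                "statistic": res.t_statistics[i], "r_squared": res.r_squared,
                "beta": res.coefficients[1 + i], "p_value": res.p_values[i],
                "n_perm": n_perm, "seed": seed,
            })
    else:
        for var, mat in clim.items():
            mat = mat if mat.labels == labels else mat.reorder(labels)
            try:
                res = mmrr(y, [mat, geo_mmrr], n_perm=n_perm, seed=seed,
                           names=[var, "geographic"])
            except ValidationError as exc:
                # e.g. a climate gradient exactly collinear with distance:
                # report the failure as a row instead of aborting the suite
                rows.append({
                    "test": f"ibe_{var}", "predictor": var,
                    "statistic": np.nan, "r_squared": np.nan, "beta": np.nan,
                    "p_value": np.nan, "n_perm": n_perm, "seed": seed,
                    "note": str(exc),
                })
                continue
            rows.append({
                "test": f"ibe_{var}", "predictor": var,
                "statistic": res.t_statistics[0], "r_squared": res.r_squared,
                "beta": res.coefficients[1], "p_value": res.p_values[0],
                "n_perm": n_perm, "seed": seed,
            })

    if wind is not None:
        wmat = wind.symmetrized() if not wind.symmetric else wind
        wmat = wmat if wmat.labels == labels else wmat.reorder(labels)
        res = mmrr(y, [wmat], n_perm=n_perm, seed=seed, names=["wind"])
        rows.append({
            "test": "ibr_wind", "predictor": "wind",
            "statistic": res.t_statistics[0], "r_squared": res.r_squared,
            "beta": res.coefficients[1], "p_value": res.p_values[0],
            "n_perm": n_perm, "seed": seed,
        })

    return pd.DataFrame(rows)
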
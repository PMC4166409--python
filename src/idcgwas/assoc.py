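"""Single-marker association under six models, bootstrap thresholds, MSD model selection.

The six models are the cross of covariate sets {none, PC_25, PC_50} with and
without a kinship random effect.  Fixed-effect models are ordinary least
squares with a two-sided t test on the marker coefficient.  Kinship models use
the exact mixed-model test: y = W a + x b + u + e with u ~ N(0, sg^2 K),
e ~ N(0, se^2 I); the variance ratio lambda = sg^2/se^2 is re-optimized by
restricted maximum likelihood for every marker (one-time eigendecomposition of
K, 1-D optimization in lambda), followed by a Wald F test on b.

Model choice uses a rank-based mean squared difference (MSD) between sorted
observed p-values and their uniform-order-statistic expectations i/(m+1);
significance cutoffs are the 0.01- and 0.1-percentile tails of the empirical
p-value distribution aggregated over bootstrap resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from idcgwas.genio import GenotypeMatrix

P_FLOOR = 1e-300  # avoids -log10 underflow in Manhattan output

MODEL_NAMES = ("naive", "pc25", "pc50", "kinship", "pc25+kinship", "pc50+kinship")


@dataclass(frozen=True)
class ModelSpec:
    """One of the six association models."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")

    @property
    def pc_threshold(self) -> float | None:
        if self.name.startswith("pc25"):
            return 0.25
        if self.name.startswith("pc50"):
            return 0.50
        return None

    @property
    def uses_kinship(self) -> bool:
        return "kinship" in self.name


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if covariates is None or covariates.size == 0:
        return ones
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != n:
        cov = cov.T
    return np.hstack([ones, cov])


# ---------------------------------------------------------------------------
# Fixed-effect (OLS) tests
# ---------------------------------------------------------------------------

@dataclass
class FixedFit:
    beta: float
    se: float
    p_value: float
    degenerate: bool = False


def fit_marker_fixed(
    y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None = None
) -> FixedFit:
    """OLS of y on [intercept, covariates, marker]; two-sided t test on the marker.

    A marker collinear with the covariates (including a constant marker) is
    flagged degenerate with p = 1.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    W = _design(covariates, n)
    M = np.column_stack([W, np.asarray(x, dtype=float)])
    p = M.shape[1]
    if n <= p:
        raise ValueError("need n > number of covariates + 2")
    coef, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < p:
        return FixedFit(beta=np.nan, se=np.nan, p_value=1.0, degenerate=True)
    resid = y - M @ coef
    df = n - p
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(M.T @ M)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    if se == 0.0:
        return FixedFit(beta=float(coef[-1]), se=0.0, p_value=P_FLOOR)
    t = coef[-1] / se
    pval = max(float(2.0 * stats.t.sf(abs(t), df)), P_FLOOR)
    return FixedFit(beta=float(coef[-1]), se=se, p_value=pval)


def ols_scan(
    y: np.ndarray, X: np.ndarray, covariates: np.ndarray | None = None
) -> pd.DataFrame:
    """Vectorized per-marker OLS via Frisch-Waugh-Lovell residualization.

    Numerically identical to :func:`fit_marker_fixed` applied column-wise.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.size
    W = _design(covariates, n)
    q, _ = np.linalg.qr(W)
    ry = y - q @ (q.T @ y)
    RX = X - q @ (q.T @ X)
    sxx = np.einsum("nm,nm->m", RX, RX)
    sxy = RX.T @ ry
    syy = ry @ ry
    df = n - W.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        se = np.sqrt(np.maximum(rss, 0.0) / df / sxx)
        tstat = beta / se
    degenerate = sxx <= 1e-12 * max(float(syy), 1.0)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    pval = np.where(degenerate, 1.0, np.clip(pval, P_FLOOR, 1.0))
    beta = np.where(degenerate, np.nan, beta)
    return pd.DataFrame({"beta": beta, "se": se, "p_value": pval, "degenerate": degenerate})


# ---------------------------------------------------------------------------
# Exact mixed-model (REML) tests
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """Per-marker exact mixed-model fit."""

    lambda_: float          # variance ratio sg^2 / se^2
    sigma_g2: float
    sigma_e2: float
    loglik: float           # restricted log-likelihood (constants in lambda only)
    beta: float
    se: float
    p_value: float
    boundary: bool = False  # optimizer at lambda grid edge


class MixedModel:
    """GEMMA-style exact-test machinery sharing one eigendecomposition of K.

    Construction rotates y and the covariate design into the eigenbasis of K;
    each marker then requires only a 1-D REML optimization over the variance
    ratio lambda with O(n) likelihood evaluations.
    """

    LOG10_LAMBDA_RANGE = (-6.0, 6.0)
    GRID_STEP = 0.1

    def __init__(self, y: np.ndarray, covariates: np.ndarray | None, K: np.ndarray):
        y = np.asarray(y, dtype=float)
        K = np.asarray(K, dtype=float)
        n = y.size
        if K.shape != (n, n):
            raise ValueError("kinship dimensions do not match phenotype length")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        d, U = np.linalg.eigh(K)
        if d.min() < -1e-8 * max(d.max(), 1.0):
            raise ValueError("kinship matrix is not positive semi-definite")
        self.d = np.clip(d, 0.0, None)
        self.n = n
        W = _design(covariates, n)
        self.p0 = W.shape[1]
        self.U = U
        self.yt = U.T @ y
        self.Wt = U.T @ W
        self.yt2 = self.yt**2

    # -- core: restricted log-likelihood and Wald statistics at given lambda --

    def _stats(self, lam: np.ndarray, Xt: np.ndarray, cols: np.ndarray) -> dict:
        """Evaluate REML loglik + Wald stats at per-marker lambda.

        lam: (b,) per-marker variance ratios; Xt: rotated marker matrix (n, m);
        cols: (b,) column indices into Xt.
        """
        v = 1.0 / (lam[:, None] * self.d[None, :] + 1.0)      # (b, n)
        Wt, yt = self.Wt, self.yt
        xc = Xt[:, cols]                                      # (n, b)
        A = np.einsum("bn,np,nq->bpq", v, Wt, Wt)
        awy = np.einsum("bn,n,np->bp", v, yt, Wt)
        awx = np.einsum("bn,nb,np->bp", v, xc, Wt)
        ayy = v @ self.yt2
        axx = np.einsum("bn,nb->b", v, xc**2)
        axy = np.einsum("bn,n,nb->b", v, yt, xc)
        rhs = np.stack([awy, awx], axis=2)                    # (b, p0, 2)
        sol = np.linalg.solve(A, rhs)
        alpha0, qx = sol[..., 0], sol[..., 1]
        S = axx - np.einsum("bp,bp->b", awx, qx)
        bnum = axy - np.einsum("bp,bp->b", awx, alpha0)
        r0 = ayy - np.einsum("bp,bp->b", awy, alpha0)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = bnum / S
            rss = np.maximum(r0 - bnum**2 / S, 1e-300)
        sign, logdetA = np.linalg.slogdet(A)
        log_v = np.sum(np.log1p(lam[:, None] * self.d[None, :]), axis=1)
        p = self.p0 + 1
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = -0.5 * (log_v + logdetA + np.log(np.maximum(S, 1e-300))
                         + (self.n - p) * np.log(rss))
        return {"ll": ll, "beta": beta, "S": S, "rss": rss}

    def _grid_ll(self, Xt: np.ndarray, grid: np.ndarray) -> np.ndarray:
        """Restricted log-likelihood on a shared lambda grid: (n_grid, m)."""
        Wt, yt, d = self.Wt, self.yt, self.d
        m = Xt.shape[1]
        Xt2 = Xt**2
        p = self.p0 + 1
        out = np.empty((grid.size, m))
        for gi, lam in enumerate(grid):
            v = 1.0 / (lam * d + 1.0)
            Wv = Wt * v[:, None]
            A = Wt.T @ Wv
            c, low = cho_factor(A)
            awy = Wv.T @ yt
            ayy = v @ self.yt2
            AWX = Wv.T @ Xt
            axx = v @ Xt2
            axy = (v * yt) @ Xt
            qx = cho_solve((c, low), AWX)
            alpha0 = cho_solve((c, low), awy)
            S = axx - np.einsum("pm,pm->m", AWX, qx)
            bnum = axy - awy @ qx
            r0 = ayy - awy @ alpha0
            with np.errstate(divide="ignore", invalid="ignore"):
                rss = np.maximum(r0 - bnum**2 / np.where(S > 0, S, np.inf), 1e-300)
            logdetA = 2.0 * np.sum(np.log(np.diag(c)))
            log_v = np.sum(np.log1p(lam * d))
            with np.errstate(divide="ignore", invalid="ignore"):
                out[gi] = -0.5 * (log_v + logdetA + np.log(np.maximum(S, 1e-300))
                                  + (self.n - p) * np.log(rss))
            out[gi, S <= 1e-12] = -np.inf
        return out

    def scan(self, X: np.ndarray, chunk: int = 2000) -> pd.DataFrame:
        """Exact-test scan over marker columns of X.

        Per-marker REML lambda is located on a log10 grid (step 0.1), refined
        by quadratic interpolation, and final Wald statistics are evaluated at
        the refined lambda (falling back to the grid optimum where refinement
        does not improve the restricted likelihood).
        """
        X = np.asarray(X, dtype=float)
        Xt = self.U.T @ X
        m = X.shape[1]
        lo, hi = self.LOG10_LAMBDA_RANGE
        grid_log = np.arange(lo, hi + 1e-9, self.GRID_STEP)
        grid = 10.0**grid_log
        ll = self._grid_ll(Xt, grid)
        best = np.argmax(ll, axis=0)
        degenerate = ~np.isfinite(ll[best, np.arange(m)])
        # quadratic refinement in log10(lambda)
        i0 = np.clip(best, 1, grid.size - 2)
        l1, l2, l3 = ll[i0 - 1, np.arange(m)], ll[i0, np.arange(m)], ll[i0 + 1, np.arange(m)]
        denom = l1 - 2.0 * l2 + l3
        with np.errstate(divide="ignore", invalid="ignore"):
            shift = 0.5 * (l1 - l3) / denom
        shift = np.where(np.isfinite(shift) & (np.abs(shift) <= 1.0), shift, 0.0)
        lam_ref = 10.0 ** (grid_log[i0] + shift * self.GRID_STEP)
        lam_grid = grid[best]
        boundary = (best == 0) | (best == grid.size - 1)

        p = self.p0 + 1
        res = {k: np.empty(m) for k in ("lambda_", "beta", "se", "p_value", "loglik")}
        for start in range(0, m, chunk):
            cols = np.arange(start, min(start + chunk, m))
            st_ref = self._stats(lam_ref[cols], Xt, cols)
            worse = st_ref["ll"] < ll[best[cols], cols]
            lam_fin = np.where(worse, lam_grid[cols], lam_ref[cols])
            if worse.any():
                st_g = self._stats(lam_fin, Xt, cols)
                for k in st_ref:
                    st_ref[k] = np.where(worse, st_g[k], st_ref[k])
            sigma2 = st_ref["rss"] / (self.n - p)
            with np.errstate(divide="ignore", invalid="ignore"):
                se2 = sigma2 / st_ref["S"]
                fstat = st_ref["beta"] ** 2 / se2
            pv = stats.f.sf(fstat, 1, self.n - p)
            res["lambda_"][cols] = lam_fin
            res["beta"][cols] = st_ref["beta"]
            res["se"][cols] = np.sqrt(se2)
            res["p_value"][cols] = np.clip(pv, P_FLOOR, 1.0)
            res["loglik"][cols] = st_ref["ll"]
        res["p_value"][degenerate] = 1.0
        res["beta"][degenerate] = np.nan
        out = pd.DataFrame(res)
        out["degenerate"] = degenerate
        out["boundary"] = boundary
        return out

    def fit_one(self, x: np.ndarray) -> LMMFit:
        """Exact mixed-model fit for a single marker (bounded scalar optimization)."""
        x = np.asarray(x, dtype=float).reshape(-1, 1)
        Xt = self.U.T @ x
        cols = np.array([0])

        def neg_ll(loglam: float) -> float:
            return -float(self._stats(np.array([10.0**loglam]), Xt, cols)["ll"][0])

        lo, hi = self.LOG10_LAMBDA_RANGE
        coarse = np.arange(lo, hi + 1e-9, 0.5)
        vals = np.array([neg_ll(g) for g in coarse])
        i = int(np.argmin(vals))
        a, b = coarse[max(i - 1, 0)], coarse[min(i + 1, coarse.size - 1)]
        opt = minimize_scalar(neg_ll, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-7})
        loglam = float(opt.x)
        lam = 10.0**loglam
        st = self._stats(np.array([lam]), Xt, cols)
        p = self.p0 + 1
        if not np.isfinite(st["ll"][0]):
            return LMMFit(lam, np.nan, np.nan, -np.inf, np.nan, np.nan, 1.0, True)
        sigma_e2 = float(st["rss"][0]) / (self.n - p)
        se = float(np.sqrt(sigma_e2 / st["S"][0]))
        fstat = float(st["beta"][0]) ** 2 / se**2
        pv = max(float(stats.f.sf(fstat, 1, self.n - p)), P_FLOOR)
        boundary = loglam <= lo + 1e-3 or loglam >= hi - 1e-3
        return LMMFit(
            lambda_=lam,
            sigma_g2=lam * sigma_e2,
            sigma_e2=sigma_e2,
            loglik=float(st["ll"][0]),
            beta=float(st["beta"][0]),
            se=se,
            p_value=pv,
            boundary=boundary,
        )

    def fit_null(self) -> tuple[float, float, float]:
        """REML variance ratio of the covariates-only model: (lambda, sg^2, se^2)."""
        d, Wt, yt = self.d, self.Wt, self.yt
        p0, n = self.p0, self.n

        def neg_ll(loglam: float) -> float:
            lam = 10.0**loglam
            v = 1.0 / (lam * d + 1.0)
            Wv = Wt * v[:, None]
            A = Wt.T @ Wv
            c, low = cho_factor(A)
            awy = Wv.T @ yt
            alpha0 = cho_solve((c, low), awy)
            rss = max(float(v @ self.yt2 - awy @ alpha0), 1e-300)
            logdetA = 2.0 * np.sum(np.log(np.diag(c)))
            return 0.5 * (np.sum(np.log1p(lam * d)) + logdetA + (n - p0) * np.log(rss))

        lo, hi = self.LOG10_LAMBDA_RANGE
        coarse = np.arange(lo, hi + 1e-9, 0.5)
        i = int(np.argmin([neg_ll(g) for g in coarse]))
        a, b = coarse[max(i - 1, 0)], coarse[min(i + 1, coarse.size - 1)]
        opt = minimize_scalar(neg_ll, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-7})
        lam = 10.0 ** float(opt.x)
        v = 1.0 / (lam * d + 1.0)
        Wv = Wt * v[:, None]
        awy = Wv.T @ yt
        alpha0 = np.linalg.solve(Wt.T @ Wv, awy)
        sigma_e2 = max(float(v @ self.yt2 - awy @ alpha0), 1e-300) / (n - p0)
        return lam, lam * sigma_e2, sigma_e2


def fit_marker_lmm(
    y: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray,
) -> LMMFit:
    """Exact mixed-model test for one marker (convenience wrapper)."""
    return MixedModel(y, covariates, K).fit_one(x)


# ---------------------------------------------------------------------------
# Model running and selection
# ---------------------------------------------------------------------------

def model_covariates(model: ModelSpec, structure, n_pc25: int, n_pc50: int):
    thr = model.pc_threshold
    if thr is None:
        return None
    k = n_pc25 if thr == 0.25 else n_pc50
    return structure.scores[:, :k]


def run_model(
    model: ModelSpec,
    y: np.ndarray,
    g: GenotypeMatrix,
    structure=None,
    K: np.ndarray | None = None,
    n_pc25: int | None = None,
    n_pc50: int | None = None,
) -> pd.DataFrame:
    """p-values (plus effect estimates) for all markers under one model."""
    cov = None
    if model.pc_threshold is not None:
        if structure is None or n_pc25 is None or n_pc50 is None:
            raise ValueError(f"model {model.name} needs PCA structure and PC counts")
        cov = model_covariates(model, structure, n_pc25, n_pc50)
    if model.uses_kinship:
        if K is None:
            raise ValueError(f"model {model.name} needs a kinship matrix")
        return MixedModel(y, cov, K).scan(g.dosage)
    return ols_scan(y, g.dosage, cov)


@dataclass
class MSDReport:
    """Rank-based MSD per model; smaller is closer to the uniform null."""

    msd: dict[str, float]
    selected: str


def msd(p: np.ndarray) -> float:
    """Mean squared difference between sorted p-values and i/(m+1) expectations."""
    p = np.sort(np.asarray(p, dtype=float))
    m = p.size
    if m == 0:
        raise ValueError("MSD undefined for an empty p-value vector")
    expected = np.arange(1, m + 1) / (m + 1)
    return float(np.mean((p - expected) ** 2))


def msd_select(p_by_model: dict[str, np.ndarray]) -> MSDReport:
    if not p_by_model:
        raise ValueError("no models supplied")
    table = {name: msd(p) for name, p in p_by_model.items()}
    selected = min(table, key=table.get)
    return MSDReport(msd=table, selected=selected)


def genomic_lambda(p: np.ndarray) -> float:
    """Genomic-control inflation factor from a p-value vector."""
    chi2 = stats.chi2.isf(np.clip(p, P_FLOOR, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


# ---------------------------------------------------------------------------
# Per-marker summary statistics (allele means, additive effect, R^2)
# ---------------------------------------------------------------------------

def marker_stats(y_raw: np.ndarray, g: GenotypeMatrix) -> pd.DataFrame:
    """Allelic means, mean difference, additive effect, simple-regression R^2, MAF.

    Allelic means use homozygote classes only (dosage 0 = reference class,
    dosage 2 = variant class); heterozygotes are excluded from the means but
    contribute to the regression R^2.  additive effect = (variant mean -
    reference mean) / 2; mean difference is its absolute doubled counterpart.
    Markers missing a homozygote class get NaN mean statistics.
    """
    y = np.asarray(y_raw, dtype=float)
    d = g.dosage
    m = g.n_markers
    ref_mean = np.full(m, np.nan)
    var_mean = np.full(m, np.nan)
    r2 = np.full(m, np.nan)
    for j in range(m):
        col = d[:, j]
        obs = ~np.isnan(col)
        ref = obs & (col == 0)
        var = obs & (col == 2)
        if ref.any():
            ref_mean[j] = y[ref].mean()
        if var.any():
            var_mean[j] = y[var].mean()
        if obs.sum() >= 3 and np.nanstd(col[obs]) > 0:
            r = np.corrcoef(col[obs], y[obs])[0, 1]
            r2[j] = 100.0 * r * r
    additive = (var_mean - ref_mean) / 2.0
    return pd.DataFrame(
        {
            "id": g.markers["id"],
            "chrom": g.markers["chrom"],
            "pos": g.markers["pos"],
            "ref": g.markers["ref"],
            "alt": g.markers["alt"],
            "maf_pct": 100.0 * g.maf(),
            "ref_mean": ref_mean,
            "var_mean": var_mean,
            "mean_difference": np.abs(var_mean - ref_mean),
            "additive_effect": additive,
            "r2_pct": r2,
        }
    )


# ---------------------------------------------------------------------------
# Bootstrap empirical thresholds
# ---------------------------------------------------------------------------

@dataclass
class ThresholdSet:
    """Percentile-tail p-value cutoffs from bootstrap resampling.

    ``cutoffs`` maps quantile fraction (0.0001 for the 0.01 percentile, 0.001
    for the 0.1 percentile) to a p-value cutoff; markers with p <= cutoff are
    significant at that level.
    """

    cutoffs: dict[float, float]
    n_boot: int
    aggregator: str = "mean"
    quantile_method: str = "linear"  # type-7 interpolation

    def significant(self, p: np.ndarray, level: float) -> np.ndarray:
        return np.asarray(p) <= self.cutoffs[level]


def bootstrap_thresholds(
    p: np.ndarray,
    levels: tuple[float, ...] = (0.0001, 0.001),
    n_boot: int = 10_000,
    seed: int | None = None,
    aggregator: str = "mean",
) -> ThresholdSet:
    """Empirical percentile-tail cutoffs over ``n_boot`` bootstrap resamples.

    Each resample draws m p-values with replacement; its level-quantile
    (type-7 linear interpolation) is recorded and the cutoff is the mean (or
    median) of the n_boot quantiles.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    for lev in levels:
        if not 0.0 < lev < 1.0:
            raise ValueError(f"quantile level {lev} outside (0, 1)")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if m < 1.0 / min(levels):
        warnings.warn(
            f"only {m} p-values for quantile level {min(levels)}; the extreme "
            "tail quantile rests on interpolation between the smallest order statistics",
            stacklevel=2,
        )
    if aggregator not in ("mean", "median"):
        raise ValueError("aggregator must be 'mean' or 'median'")
    rng = np.random.default_rng(seed)
    qlevels = np.asarray(levels, dtype=float)
    quants = np.empty((len(levels), n_boot))
    chunk = max(1, int(5_000_000 // max(m, 1)))
    for start in range(0, n_boot, chunk):
        b = min(chunk, n_boot - start)
        samp = p[rng.integers(0, m, size=(b, m))]
        quants[:, start : start + b] = np.quantile(samp, qlevels, axis=1)
    agg = np.mean if aggregator == "mean" else np.median
    cutoffs = {float(lev): float(agg(quants[i])) for i, lev in enumerate(levels)}
    return ThresholdSet(cutoffs=cutoffs, n_boot=n_boot, aggregator=aggregator)
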
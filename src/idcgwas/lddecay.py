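"""Structure-corrected pairwise LD (partial r^2) and genome-wide decay fitting.

Partial r^2 between two markers is the squared Pearson correlation of their
dosage residuals after linear regression on structure covariates (principal
components); with no covariates it reduces to the plain squared allele-count
correlation.  The decay of expected r^2 with distance follows the
drift-recombination expectation

    E(r^2) = [(10 + C) / ((2 + C)(11 + C))]
             * [1 + ((3 + C)(12 + 12 C + C^2)) / (n (2 + C)(11 + C))]

with C = rho * distance, where rho (the free recombination-scale parameter)
is fitted by nonlinear least squares and n is the sample size.  Note the
curve saturates below 0.5 as C -> 0, so query levels above that ceiling have
no crossing distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from idcgwas.genio import GenotypeMatrix


def residualize(X: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of each column of X after OLS on [intercept, covariates]."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    n = X.shape[0]
    W = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        W = np.hstack([W, cov])
    q, _ = np.linalg.qr(W)
    return X - q @ (q.T @ X)


def partial_r2(
    x1: np.ndarray, x2: np.ndarray, covariates: np.ndarray | None = None
) -> float:
    """Squared correlation of covariate-adjusted dosages; NaN if a residual is constant."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("marker vectors must have equal length")
    R = residualize(np.column_stack([x1, x2]), covariates)
    v = np.einsum("nm,nm->m", R, R)
    if np.any(v <= 1e-12 * x1.size):
        return float("nan")
    r = (R[:, 0] @ R[:, 1]) / np.sqrt(v[0] * v[1])
    return float(r * r)


def pairwise_partial_r2(
    X: np.ndarray, covariates: np.ndarray | None = None
) -> np.ndarray:
    """Partial-r^2 matrix over the columns of X (NaN rows for constant residuals)."""
    R = residualize(X, covariates)
    norms = np.sqrt(np.einsum("nm,nm->m", R, R))
    bad = norms <= 1e-12 * np.sqrt(X.shape[0])
    norms = np.where(bad, 1.0, norms)
    C = (R / norms).T @ (R / norms)
    out = C**2
    out[bad, :] = np.nan
    out[:, bad] = np.nan
    return out


# ---------------------------------------------------------------------------
# Decay-curve fitting
# ---------------------------------------------------------------------------

def expected_r2(C: np.ndarray | float, n: int) -> np.ndarray | float:
    """Drift-recombination expectation of r^2 at population recombination C."""
    C = np.asarray(C, dtype=float)
    term1 = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    term2 = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (
        n * (2.0 + C) * (11.0 + C)
    )
    out = term1 * term2
    return float(out) if out.ndim == 0 else out


@dataclass
class DecayFit:
    """Fitted decay of expected r^2 with physical distance."""

    rho: float                     # per-bp recombination-scale coefficient
    n: int                         # sample size used in the expectation
    sse: float
    crossings: dict[float, float | None]  # r^2 level -> distance (bp), None if unattained

    def predict(self, distance_bp: np.ndarray | float) -> np.ndarray | float:
        return expected_r2(self.rho * np.asarray(distance_bp, dtype=float), self.n)


def fit_decay(
    distances_bp: np.ndarray,
    r2: np.ndarray,
    n: int,
    query_levels: tuple[float, ...] = (0.7, 0.2, 0.1),
    max_search_bp: float = 1e10,
) -> DecayFit:
    """Least-squares fit of the expected-r^2 curve over pairwise observations.

    A multi-start search over a log-spaced rho grid is refined by bounded
    scalar minimization (relative SSE tolerance ~1e-10).  Crossing distances
    are reported for each query level the fitted curve actually attains.
    """
    dist = np.asarray(distances_bp, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    ok = np.isfinite(dist) & np.isfinite(r2) & (dist >= 0)
    dist, r2 = dist[ok], r2[ok]
    if dist.size < 10:
        raise ValueError("need at least 10 pairs to fit the decay curve")
    pos = dist[dist > 0]
    if pos.size and np.log10(pos.max() / pos.min()) < 2.0:
        raise ValueError("pair distances must span at least 2 orders of magnitude")

    def sse(log10_rho: float) -> float:
        pred = expected_r2(10.0**log10_rho * dist, n)
        err = r2 - pred
        return float(err @ err)

    grid = np.linspace(-12.0, -3.0, 46)
    vals = np.array([sse(g) for g in grid])
    if not np.isfinite(vals).any():
        raise RuntimeError("decay fit failed to evaluate on the rho grid")
    i = int(np.argmin(vals))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
    opt = minimize_scalar(sse, bounds=(a, b), method="bounded", options={"xatol": 1e-10})
    if not opt.success:
        raise RuntimeError(f"decay-curve optimization did not converge: {opt.message}")
    rho = 10.0 ** float(opt.x)

    crossings: dict[float, float | None] = {}
    ceiling = expected_r2(0.0, n)
    for lev in query_levels:
        if lev >= ceiling or lev <= 0.0:
            crossings[lev] = None
            continue
        f = lambda x: expected_r2(rho * x, n) - lev  # noqa: E731
        if f(max_search_bp) > 0:
            crossings[lev] = None
            continue
        crossings[lev] = float(brentq(f, 0.0, max_search_bp, xtol=1.0))
    return DecayFit(rho=rho, n=n, sse=float(opt.fun), crossings=crossings)


def binned_decay(
    distances_bp: np.ndarray, r2: np.ndarray, n_bins: int = 25
) -> pd.DataFrame:
    """Mean observed r^2 in log-spaced distance bins (diagnostic companion to the fit)."""
    dist = np.asarray(distances_bp, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    ok = np.isfinite(r2) & (dist > 0)
    dist, r2 = dist[ok], r2[ok]
    edges = np.logspace(np.log10(dist.min()), np.log10(dist.max()), n_bins + 1)
    idx = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            rows.append(
                {
                    "bin_mid_bp": float(np.sqrt(edges[b] * edges[b + 1])),
                    "mean_r2": float(r2[sel].mean()),
                    "n_pairs": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pair sampling
# ---------------------------------------------------------------------------

def sample_pairs(
    g: GenotypeMatrix,
    max_pairs: int,
    max_distance: int,
    seed: int | None = None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Uniform random intra-chromosomal marker pairs within ``max_distance``.

    Returns a pair table (chrom, pos1, pos2, distance_bp, r2) with partial r^2
    already evaluated.  If fewer than ``max_pairs`` pairs exist, all are
    returned (no duplicates); sampling is deterministic under ``seed``.
    """
    if max_pairs < 1:
        raise ValueError("max_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    mk = g.markers
    R = residualize(g.dosage, covariates)
    norms = np.sqrt(np.einsum("nm,nm->m", R, R))
    norms = np.where(norms <= 1e-12, np.nan, norms)
    Rn = R / norms

    # enumerate candidate windows per chromosome
    pair_index: list[tuple[int, int]] = []
    counts = []
    spans = []
    for chrom, grp in mk.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        hi = np.searchsorted(pos, pos + max_distance, side="right")
        lo = np.arange(pos.size) + 1
        cnt = np.maximum(hi - lo, 0)
        spans.append((idx, pos, lo, cnt))
        counts.append(cnt.sum())
    total = int(np.sum(counts))
    if total == 0:
        return pd.DataFrame(columns=["chrom", "pos1", "pos2", "distance_bp", "r2"])

    if total <= max_pairs:
        chosen = np.arange(total)
    else:
        chosen = rng.choice(total, size=max_pairs, replace=False)
        chosen.sort()
    # map flat pair ranks to (i, j) via cumulative counts
    offsets = np.concatenate([[0], np.cumsum(counts)])
    rows = []
    for c, (idx, pos, lo, cnt) in enumerate(spans):
        sel = chosen[(chosen >= offsets[c]) & (chosen < offsets[c + 1])] - offsets[c]
        if sel.size == 0:
            continue
        cum = np.concatenate([[0], np.cumsum(cnt)])
        i_local = np.searchsorted(cum, sel, side="right") - 1
        j_local = lo[i_local] + (sel - cum[i_local])
        gi, gj = idx[i_local], idx[j_local]
        r2 = np.einsum("nk,nk->k", Rn[:, gi], Rn[:, gj]) ** 2
        chrom = mk.loc[idx[0], "chrom"]
        for a, b, v in zip(pos[i_local], pos[j_local], r2):
            rows.append((chrom, int(a), int(b), int(b - a), float(v)))
    return pd.DataFrame(rows, columns=["chrom", "pos1", "pos2", "distance_bp", "r2"])
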
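"""Stepwise marker selection, LD-chained QTL regions, epistasis and allelic combinations.

A QTL region is grown outward from a stepwise-selected lead marker along the
chromosome while the partial LD (r^2, structure-adjusted) between the current
block edge and the next adjacent marker exceeds a threshold (0.6, i.e. a
partial correlation of ~0.77).  Nearby blocks separated by < 10 kb with at
most four intervening markers not in LD with either block are merged.
Candidate genes are genes whose interval intersects a region.

Allelic combinations string together the carried allele letter at each
stepwise marker (fixed marker order); combination means on the raw 1-5 IDC
scale classify genotype groups as tolerant (mean <= 2.5), susceptible
(mean >= 3.5) or intermediate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from idcgwas.genio import GenotypeMatrix


# ---------------------------------------------------------------------------
# Stepwise regression
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    selected: list[str]
    step_p: list[float]          # partial p of each marker when it entered
    multiple_r2_pct: float
    final_p: dict[str, float]    # partial p of each retained marker in the joint model

    def __bool__(self) -> bool:
        return bool(self.selected)


def _ols(y: np.ndarray, cols: list[np.ndarray]):
    X = sm.add_constant(np.column_stack(cols)) if cols else np.ones((y.size, 1))
    return sm.OLS(y, X).fit()


def stepwise_select(
    y: np.ndarray,
    X: np.ndarray,
    ids: list[str],
    p_enter: float = 0.05,
    p_model: float = 0.05,
    eliminate: bool = True,
) -> StepwiseResult:
    """Forward stepwise selection with optional backward elimination.

    At each step the candidate with the smallest partial p-value enters if
    that p <= p_enter and the overall model F test has p <= p_model; after
    each addition any retained marker whose partial p has risen above p_enter
    is dropped.  Candidates collinear with the current model are skipped, so
    duplicated markers are selected at most once.  An empty result (no
    candidate qualifies) is valid.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    ids = list(ids)
    in_model: list[int] = []
    step_p: list[float] = []
    remaining = list(range(len(ids)))
    while remaining:
        best_j, best_p = None, np.inf
        cur_cols = [X[:, k] for k in in_model]
        for j in remaining:
            cols = cur_cols + [X[:, j]]
            M = np.column_stack([np.ones(y.size)] + cols)
            if np.linalg.matrix_rank(M) < M.shape[1]:
                continue
            fit = _ols(y, cols)
            pj = fit.pvalues[-1]
            if pj < best_p:
                best_j, best_p, best_fit = j, pj, fit
        if best_j is None or best_p > p_enter:
            break
        if best_fit.f_pvalue > p_model:
            break
        in_model.append(best_j)
        remaining.remove(best_j)
        step_p.append(float(best_p))
        if eliminate:
            while len(in_model) > 1:
                fit = _ols(y, [X[:, k] for k in in_model])
                partial = fit.pvalues[1:]
                worst = int(np.argmax(partial))
                if partial[worst] <= p_enter:
                    break
                dropped = in_model.pop(worst)
                remaining.append(dropped)
                del step_p[worst]
    if not in_model:
        return StepwiseResult([], [], 0.0, {})
    fit = _ols(y, [X[:, k] for k in in_model])
    final_p = {ids[k]: float(p) for k, p in zip(in_model, fit.pvalues[1:])}
    return StepwiseResult(
        selected=[ids[k] for k in in_model],
        step_p=step_p,
        multiple_r2_pct=float(100.0 * fit.rsquared),
        final_p=final_p,
    )


# ---------------------------------------------------------------------------
# QTL region delineation and merging
# ---------------------------------------------------------------------------

@dataclass
class QTLRegion:
    chrom: str
    start: int
    end: int
    lead_id: str
    member_ids: list[str]
    gene_ids: list[str] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def _chrom_residuals(g: GenotypeMatrix, chrom: str, covariates):
    from idcgwas.lddecay import residualize

    sel = np.flatnonzero((g.markers["chrom"] == chrom).to_numpy())
    R = residualize(g.dosage[:, sel], covariates)
    norms = np.sqrt(np.einsum("nm,nm->m", R, R))
    Rn = R / np.where(norms <= 1e-12, np.nan, norms)
    return sel, Rn


def _r2(Rn: np.ndarray, i: int, j: int) -> float:
    v = float(Rn[:, i] @ Rn[:, j]) ** 2
    return v if np.isfinite(v) else 0.0


def delineate_region(
    lead_id: str,
    g: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    r2_threshold: float = 0.6,
    anchor: str = "edge",
) -> QTLRegion:
    """Grow an LD block outward from ``lead_id`` along its chromosome.

    With ``anchor="edge"`` (default) each extension tests the partial r^2
    between the current block edge and the next adjacent marker; with
    ``anchor="lead"`` every adjacent marker is tested against the lead itself.
    The region spans the outermost member-marker positions; a lead in LD with
    neither neighbour yields a single-marker region (start = end = lead).
    """
    if anchor not in ("edge", "lead"):
        raise ValueError("anchor must be 'edge' or 'lead'")
    mk = g.markers
    hit = mk.index[mk["id"] == lead_id]
    if len(hit) == 0:
        raise KeyError(f"lead marker {lead_id!r} not found")
    chrom = mk.loc[hit[0], "chrom"]
    sel, Rn = _chrom_residuals(g, chrom, covariates)
    local = {g_idx: k for k, g_idx in enumerate(sel)}
    lead_local = local[hit[0]]
    m_c = sel.size

    left = lead_local
    while left > 0:
        ref = left if anchor == "edge" else lead_local
        if _r2(Rn, ref, left - 1) > r2_threshold:
            left -= 1
        else:
            break
    right = lead_local
    while right < m_c - 1:
        ref = right if anchor == "edge" else lead_local
        if _r2(Rn, ref, right + 1) > r2_threshold:
            right += 1
        else:
            break
    members = sel[left : right + 1]
    return QTLRegion(
        chrom=str(chrom),
        start=int(mk.loc[members[0], "pos"]),
        end=int(mk.loc[members[-1], "pos"]),
        lead_id=lead_id,
        member_ids=mk.loc[members, "id"].tolist(),
    )


def merge_blocks(
    blocks: list[QTLRegion],
    g: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    gap_bp: int = 10_000,
    max_nonld_markers: int = 4,
    r2_threshold: float = 0.6,
    rule: str = "and",
) -> list[QTLRegion]:
    """Merge adjacent same-chromosome blocks separated by short non-LD gaps.

    With the default ``rule="and"`` two blocks merge when the end-to-start gap
    is < ``gap_bp`` AND at most ``max_nonld_markers`` markers strictly between
    them are not in LD (partial r^2 <= threshold) with any member of either
    block; ``rule="or"`` merges when either condition holds.  Repeats to a
    fixpoint.  Intervening markers join the merged member list; the merged
    lead is the left block's lead.
    """
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    mk = g.markers
    out: list[QTLRegion] = []
    by_chrom: dict[str, list[QTLRegion]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, blist in by_chrom.items():
        blist = sorted(blist, key=lambda b: b.start)
        sel, Rn = _chrom_residuals(g, chrom, covariates)
        local_pos = mk.loc[sel, "pos"].to_numpy()
        local_id = mk.loc[sel, "id"].to_numpy()
        id_to_local = {mid: k for k, mid in enumerate(local_id)}

        changed = True
        while changed:
            changed = False
            merged: list[QTLRegion] = [blist[0]]
            for nxt in blist[1:]:
                cur = merged[-1]
                gap = nxt.start - cur.end
                between = np.flatnonzero((local_pos > cur.end) & (local_pos < nxt.start))
                block_members = [id_to_local[i] for i in cur.member_ids + nxt.member_ids]
                n_nonld = 0
                for k in between:
                    best = max((_r2(Rn, k, b) for b in block_members), default=0.0)
                    if best <= r2_threshold:
                        n_nonld += 1
                gap_ok = gap < gap_bp
                count_ok = n_nonld <= max_nonld_markers
                do_merge = (gap_ok and count_ok) if rule == "and" else (gap_ok or count_ok)
                if do_merge:
                    members = (
                        cur.member_ids
                        + [local_id[k] for k in between]
                        + nxt.member_ids
                    )
                    merged[-1] = QTLRegion(
                        chrom=chrom,
                        start=cur.start,
                        end=nxt.end,
                        lead_id=cur.lead_id,
                        member_ids=members,
                        gene_ids=sorted(set(cur.gene_ids) | set(nxt.gene_ids)),
                    )
                    changed = True
                else:
                    merged.append(nxt)
            blist = merged
        out.extend(blist)
    return sorted(out, key=lambda b: (b.chrom, b.start))


def overlap_genes(region: QTLRegion, genes: pd.DataFrame) -> list[str]:
    """Gene ids whose [start, end] interval intersects the region (1-based closed)."""
    sel = (
        (genes["chrom"] == region.chrom)
        & (genes["start"] <= region.end)
        & (genes["end"] >= region.start)
    )
    return genes.loc[sel, "gene_id"].tolist()


def regions_to_bed(regions: list[QTLRegion]) -> pd.DataFrame:
    """Regions as BED (0-based half-open) with the lead marker in the name column."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start - 1 for r in regions],
            "end": [r.end for r in regions],
            "name": [r.lead_id for r in regions],
        }
    )


# ---------------------------------------------------------------------------
# Epistasis
# ---------------------------------------------------------------------------

@dataclass
class EpistasisResult:
    marker_a: str
    marker_b: str
    interaction_beta: float
    p_value: float
    significant: bool
    degenerate: bool = False


def epistasis_scan(
    y: np.ndarray,
    X: np.ndarray,
    ids: list[str],
    covariates: np.ndarray | None = None,
    alpha: float = 1e-3,
) -> list[EpistasisResult]:
    """All-pairs interaction GLM: y ~ covariates + m1 + m2 + m1*m2.

    The interaction term's two-sided p-value is flagged significant at
    ``alpha``; collinear pairs are reported degenerate with p = 1.  Exactly
    k(k-1)/2 results are returned for k markers.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if len(ids) < 2:
        raise ValueError("epistasis scan needs at least 2 markers")
    base = [np.ones(y.size)]
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != y.size:
            cov = cov.T
        base.extend(cov.T)
    results = []
    for a, b in itertools.combinations(range(len(ids)), 2):
        xa, xb = X[:, a], X[:, b]
        M = np.column_stack(base + [xa, xb, xa * xb])
        if np.linalg.matrix_rank(M) < M.shape[1]:
            results.append(
                EpistasisResult(ids[a], ids[b], np.nan, 1.0, False, degenerate=True)
            )
            continue
        fit = sm.OLS(y, M).fit()
        pv = float(fit.pvalues[-1])
        results.append(
            EpistasisResult(
                marker_a=ids[a],
                marker_b=ids[b],
                interaction_beta=float(fit.params[-1]),
                p_value=pv,
                significant=pv <= alpha,
            )
        )
    return results


def epistasis_frame(results: list[EpistasisResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker_a": [r.marker_a for r in results],
            "marker_b": [r.marker_b for r in results],
            "interaction_beta": [r.interaction_beta for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Allelic combinations
# ---------------------------------------------------------------------------

@dataclass
class AlleleCombo:
    combination: str     # one allele letter per stepwise marker, fixed order
    n: int
    min: float
    max: float
    mean: float
    sd: float | None     # sample SD (n-1); absent for single-member groups
    tolerance_class: str  # tolerant / intermediate / susceptible


def allele_combos(
    g: GenotypeMatrix,
    marker_ids: list[str],
    y_raw: np.ndarray,
    t_low: float = 2.5,
    t_high: float = 3.5,
) -> tuple[list[AlleleCombo], int]:
    """Group samples by carried-allele strings over the stepwise markers.

    Samples heterozygous or missing at any selected marker are excluded (their
    count is returned).  Classification is inclusive: mean <= t_low is
    tolerant, mean >= t_high susceptible, otherwise intermediate.
    """
    y = np.asarray(y_raw, dtype=float)
    mk = g.markers.set_index("id")
    cols, refs, alts = [], [], []
    for mid in marker_ids:
        if mid not in mk.index:
            raise KeyError(f"marker {mid!r} not in genotype matrix")
        j = int(g.markers.index[g.markers["id"] == mid][0])
        cols.append(g.dosage[:, j])
        refs.append(mk.loc[mid, "ref"])
        alts.append(mk.loc[mid, "alt"])
    D = np.column_stack(cols)
    eligible = np.all((D == 0) | (D == 2), axis=1)
    n_excluded = int((~eligible).sum())
    if not eligible.any():
        raise ValueError("no samples are homozygous and called at every selected marker")
    groups: dict[str, list[float]] = {}
    for i in np.flatnonzero(eligible):
        letters = [alts[k] if D[i, k] == 2 else refs[k] for k in range(len(marker_ids))]
        groups.setdefault("".join(letters), []).append(float(y[i]))
    combos = []
    for combo, vals in sorted(groups.items(), key=lambda kv: np.mean(kv[1])):
        arr = np.asarray(vals)
        mean = float(arr.mean())
        if mean <= t_low:
            cls = "tolerant"
        elif mean >= t_high:
            cls = "susceptible"
        else:
            cls = "intermediate"
        combos.append(
            AlleleCombo(
                combination=combo,
                n=arr.size,
                min=float(arr.min()),
                max=float(arr.max()),
                mean=mean,
                sd=float(arr.std(ddof=1)) if arr.size > 1 else None,
                tolerance_class=cls,
            )
        )
    return combos, n_excluded


def classify_mean(mean: float, t_low: float = 2.5, t_high: float = 3.5) -> str:
    """Tolerance class of a combination mean under the inclusive thresholds."""
    if mean <= t_low:
        return "tolerant"
    if mean >= t_high:
        return "susceptible"
    return "intermediate"


def combos_frame(combos: list[AlleleCombo]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "combination": [c.combination for c in combos],
            "n": [c.n for c in combos],
            "min": [c.min for c in combos],
            "max": [c.max for c in combos],
            "mean": [c.mean for c in combos],
            "sd": [c.sd for c in combos],
            "class": [c.tolerance_class for c in combos],
        }
    )
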
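"""Threshold-free transcription-factor activity (TFA) screening.

For one (motif, comparison, direction) cell the screen asks whether genes of
high target propensity are over-represented among the most differentially
expressed genes — without fixing either "high" threshold in advance.  Genes
are ranked twice: by signed scaled SAM score (descending for the up-regulated
screen, ascending for down) and by descending target propensity.  For every
pair of rank thresholds (r_s, r_t) the 2x2 overlap table is scored with the
Yates-corrected chi-square; tables whose expected overlap is <= ``min_expected``
genes, or whose observed overlap does not exceed its expectation, are skipped.
The test statistic is the maximum chi-square over all admissible threshold
pairs, refined by incrementally removing the top SAM-ranked genes and
re-maximising (true targets need not hold the very top ranks).

Significance comes from a permutation null: the propensity ranking is
randomised relative to the SAM ranking and the identical maximisation
(constraints and removal scan included) is recomputed.  Because -log10 of the
empirical tail probability is close to linear in the max chi-square, an OLS
fit on the null sample extrapolates P-values far beyond the permutation
resolution.

The maximisation runs in O(G^2) per table grid via incremental prefix counts
over the two sorted orders (numba-compiled); with ``grid_step=1`` it is exact
over all threshold pairs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .expression import GeneScoreTable

__all__ = [
    "RankedInput",
    "TFAResult",
    "yates_chi_square",
    "default_grid_step",
    "max_chi_square",
    "removal_scan",
    "null_distribution",
    "extrapolate_logp",
    "tfa_screen",
    "ranked_input",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_EXPECTED = 10.0
DEFAULT_N_PERM = 10000
#: number of removal depths evaluated (including depth 0)
DEFAULT_N_DEPTHS = 5


def yates_chi_square(a: float, b: float, c: float, d: float) -> float:
    """Yates-corrected chi-square of the 2x2 table [[a, b], [c, d]].

    Returns 0 (with a debug log) when any margin is zero, since such tables
    are excluded by the screen's admissibility constraints anyway.
    """
    n = a + b + c + d
    if n <= 0:
        raise ValueError("empty table")
    m1, m2, m3, m4 = a + b, c + d, a + c, b + d
    if min(m1, m2, m3, m4) == 0:
        logger.debug("zero margin in 2x2 table; chi-square set to 0")
        return 0.0
    num = max(0.0, abs(a * d - b * c) - n / 2.0)
    return n * num * num / (m1 * m2 * m3 * m4)


def default_grid_step(n: int) -> int:
    """Rank-grid step: exact (1) up to 2000 genes, else ceil(N/2000)."""
    return 1 if n <= 2000 else math.ceil(n / 2000)


@dataclass
class RankedInput:
    """The two gene rankings feeding one screen cell.

    ``tp_pos_by_sam_rank[i]`` is the 0-based position in the propensity
    ranking of the gene holding SAM rank i; it fully determines the overlap
    tables.
    """

    genes_by_sam_rank: list[str]
    tp_pos_by_sam_rank: np.ndarray

    @property
    def n(self) -> int:
        return self.tp_pos_by_sam_rank.size


def ranked_input(z: pd.Series, tp: pd.Series, direction: str = "up") -> RankedInput:
    """Build a RankedInput from signed scaled SAM scores and propensities.

    The up screen ranks genes by descending signed z, the down screen by
    ascending; propensity always descends.  Ties break by gene ID, stably.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    common = z.index.intersection(tp.index)
    missing = len(z.index.symmetric_difference(tp.index))
    if missing:
        raise ValueError(
            f"gene universes differ between scores and propensities "
            f"({missing} unmatched genes)"
        )
    zdf = pd.DataFrame({"z": z.to_numpy(), "gene": z.index.to_numpy()})
    sam_order = zdf.sort_values(["z", "gene"], ascending=[direction == "down", True],
                                kind="mergesort")["gene"].tolist()
    tdf = pd.DataFrame({"tp": tp.to_numpy(), "gene": tp.index.to_numpy()})
    tp_order = tdf.sort_values(["tp", "gene"], ascending=[False, True],
                               kind="mergesort")["gene"].tolist()
    tp_pos = {g: i for i, g in enumerate(tp_order)}
    p = np.fromiter((tp_pos[g] for g in sam_order), dtype=np.int64,
                    count=len(sam_order))
    return RankedInput(sam_order, p)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _scan_kernel(p, step, min_expected):  # pragma: no cover - exercised via wrappers
    n = p.size
    nb = (n + step - 1) // step
    cnt = np.zeros(nb, np.int64)
    best = 0.0
    best_rs = 0
    best_rt = 0
    i = 0
    for u in range(nb):
        rs = (u + 1) * step
        if rs > n:
            rs = n
        while i < rs:
            cnt[p[i] // step] += 1
            i += 1
        acc = 0
        for v in range(nb):
            rt = (v + 1) * step
            if rt > n:
                rt = n
            acc += cnt[v]
            m2 = n - rs
            m4 = n - rt
            # Cochran-style admissibility: every cell's expected count must
            # exceed min_expected, not just the overlap cell — small expected
            # complements inflate the statistic just as unreliably
            e = rs * rt / n
            if e <= min_expected:
                continue
            if rs * m4 / n <= min_expected or m2 * rt / n <= min_expected \
                    or m2 * m4 / n <= min_expected:
                continue
            a = acc
            if a <= e:
                continue
            b = rs - a
            c = rt - a
            d = n - rs - rt + a
            num = abs(a * d - b * c) - n * 0.5
            if num < 0.0:
                num = 0.0
            chi2 = n * num * num / (rs * m2 * rt * m4)
            if chi2 > best:
                best = chi2
                best_rs = rs
                best_rt = rt
    return best, best_rs, best_rt


@njit(cache=True)
def _reduce_perm(p, k):  # pragma: no cover
    """Drop the top-k SAM genes and rank-compress the propensity positions."""
    n = p.size
    removed = np.sort(p[:k].copy())
    q = np.empty(n - k, np.int64)
    for i in range(k, n):
        v = p[i]
        lo = 0
        hi = k
        while lo < hi:
            mid = (lo + hi) // 2
            if removed[mid] < v:
                lo = mid + 1
            else:
                hi = mid
        q[i - k] = v - lo
    return q


@njit(cache=True)
def _removal_kernel(p, step, min_expected, n_depths):  # pragma: no cover
    n = p.size
    base, base_rs, base_rt = _scan_kernel(p, step, min_expected)
    best = base
    rs, rt, kb = base_rs, base_rt, 0
    if base > 0.0 and base_rs > 0 and n_depths > 1:
        max_depth = base_rs
        cap = n - int(4.0 * min_expected) - 1
        if max_depth > cap:
            max_depth = cap
        if max_depth > 0:
            kstep = (max_depth + n_depths - 2) // (n_depths - 1)
            if kstep < 1:
                kstep = 1
            k = kstep
            while k <= max_depth:
                q = _reduce_perm(p, k)
                chi2, r1, r2 = _scan_kernel(q, step, min_expected)
                if chi2 > best:
                    best = chi2
                    rs, rt, kb = r1, r2, k
                k += kstep
    return best, rs, rt, kb, base, base_rs, base_rt


@njit(cache=True)
def _null_kernel(n, n_perm, seed, step, min_expected, n_depths, use_removal):  # pragma: no cover
    np.random.seed(seed)
    out = np.empty(n_perm)
    for t in range(n_perm):
        p = np.random.permutation(n).astype(np.int64)
        if use_removal:
            out[t] = _removal_kernel(p, step, min_expected, n_depths)[0]
        else:
            out[t] = _scan_kernel(p, step, min_expected)[0]
    return out


# ---------------------------------------------------------------------------
# public wrappers
# ---------------------------------------------------------------------------

def max_chi_square(inp: RankedInput, min_expected: float = DEFAULT_MIN_EXPECTED,
                   grid_step: int | None = None) -> tuple[float, int, int]:
    """Maximum Yates chi-square over all admissible (r_s, r_t) pairs.

    Returns (chi2, r_s, r_t); (0, 0, 0) flags that no table satisfied the
    expected-overlap and observed-above-expected constraints.
    """
    n = inp.n
    if n < 4 * min_expected:
        raise ValueError(f"need at least {int(4 * min_expected)} genes, got {n}")
    step = grid_step or default_grid_step(n)
    chi2, rs, rt = _scan_kernel(inp.tp_pos_by_sam_rank, step, float(min_expected))
    return float(chi2), int(rs), int(rt)


def removal_scan(inp: RankedInput, min_expected: float = DEFAULT_MIN_EXPECTED,
                 grid_step: int | None = None,
                 n_depths: int = DEFAULT_N_DEPTHS) -> dict:
    """Max chi-square refined by incremental top-SAM-gene removal.

    Re-runs the maximisation with the top k SAM-ranked genes removed for
    ``n_depths`` depths k spaced evenly over [0, r_s of the base maximiser]
    and returns the overall maximum.  The identical scan runs inside the
    null, so observed and null statistics stay exchangeable.
    """
    n = inp.n
    step = grid_step or default_grid_step(n)
    best, rs, rt, k, base, base_rs, base_rt = _removal_kernel(
        inp.tp_pos_by_sam_rank, step, float(min_expected), n_depths
    )
    if base_rs > n - int(4 * min_expected) - 1:
        warnings.warn(
            f"removal depth truncated: base maximiser r_s={base_rs} leaves "
            f"too few genes at depth cap", RuntimeWarning,
        )
    return {
        "chi2": float(best), "r_s": int(rs), "r_t": int(rt),
        "removal_depth": int(k), "base_chi2": float(base),
        "base_r_s": int(base_rs), "base_r_t": int(base_rt),
        "admissible": base > 0.0,
    }


def null_distribution(n_genes: int, n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                      min_expected: float = DEFAULT_MIN_EXPECTED,
                      grid_step: int | None = None,
                      n_depths: int = DEFAULT_N_DEPTHS,
                      use_removal: bool = True) -> np.ndarray:
    """Sorted null sample of the max statistic under randomised rankings.

    The null permutes the propensity ranking relative to the SAM ranking, so
    it depends on the input only through the gene count and the scan
    configuration.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    step = grid_step or default_grid_step(n_genes)
    out = _null_kernel(n_genes, n_perm, seed % (2 ** 31), step,
                       float(min_expected), n_depths, use_removal)
    return np.sort(out)


def extrapolate_logp(null_sample: np.ndarray, observed: float,
                     tail_min_count: int = 10) -> tuple[float, float]:
    """-log10 P of the observed statistic via the linear null-tail fit.

    Empirical tail probabilities p(x) = #{null >= x}/n are computed at the
    distinct null values with p in [tail_min_count/n, 0.5]; OLS of -log10 p
    on x extrapolates beyond the permutation resolution.  Inside the sampled
    range the result is floored at the empirical -log10 p, so extrapolation
    never reduces significance there.  Returns (neg_log10_p, fit_r2).
    """
    null = np.sort(np.asarray(null_sample, dtype=float))
    n = null.size
    if n < 100:
        raise ValueError("null sample must have >= 100 values")
    xs = np.unique(null)
    tail = (n - np.searchsorted(null, xs, side="left")) / n
    mask = (tail >= tail_min_count / n) & (tail <= 0.5)
    n_exceed = int(n - np.searchsorted(null, observed, side="left"))
    emp_neglogp = -math.log10(n_exceed / n) if n_exceed > 0 else math.inf
    if mask.sum() < 10:
        warnings.warn(
            "fewer than 10 points in the null tail-fit window; "
            "falling back to the empirical P-value", RuntimeWarning,
        )
        if not math.isfinite(emp_neglogp):
            emp_neglogp = math.log10(n)  # below permutation resolution
        return float(emp_neglogp), float("nan")
    x = xs[mask]
    y = -np.log10(tail[mask])
    slope, intercept = np.polyfit(x, y, 1)
    fit = slope * x + intercept
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    value = slope * observed + intercept
    if n_exceed > 0:  # observed inside the sampled range
        value = max(value, emp_neglogp)
    return float(max(value, 0.0)), float(r2)


@dataclass
class TFAResult:
    pwm_id: str
    comparison_id: str
    direction: str
    chi2_max: float
    r_s: int
    r_t: int
    removal_depth: int
    base_chi2: float
    neg_log10_p: float
    fit_r2: float
    admissible: bool


def tfa_screen(score_table: GeneScoreTable,
               tp_tables: Mapping[str, pd.Series],
               directions: Sequence[str] = ("up", "down"),
               n_perm: int = DEFAULT_N_PERM,
               seed: int = 0,
               min_expected: float = DEFAULT_MIN_EXPECTED,
               grid_step: int | None = None,
               n_depths: int = DEFAULT_N_DEPTHS,
               significance: float = 2.0,
               quorum: int = 6) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen every (PWM, comparison, direction) cell and summarise per PWM.

    ``tp_tables`` maps PWM ID to a per-gene propensity Series (a propensity
    DataFrame with a ``tp`` column is also accepted).  Returns
    ``(results, summary)``: one row per cell, and per (PWM, direction) the
    mean and median -log10 P across comparisons, the count of comparisons
    with -log10 P >= ``significance`` and the >= ``quorum``-of-n consistency
    flag.  The per-PWM mean -log10 P is the candidate-ranking quantity.
    """
    genes = score_table.genes
    n = len(genes)
    step = grid_step or default_grid_step(n)
    null = null_distribution(n, n_perm=n_perm, seed=seed,
                             min_expected=min_expected, grid_step=step,
                             n_depths=n_depths)
    rows = []
    for pwm_id, tp in tp_tables.items():
        if isinstance(tp, pd.DataFrame):
            tp = tp["tp"]
        for direction in directions:
            for comp_id in score_table.z.columns:
                inp = ranked_input(score_table.z[comp_id], tp, direction)
                res = removal_scan(inp, min_expected=min_expected,
                                   grid_step=step, n_depths=n_depths)
                neglogp, r2 = extrapolate_logp(null, res["chi2"])
                rows.append(TFAResult(
                    pwm_id=pwm_id, comparison_id=comp_id, direction=direction,
                    chi2_max=res["chi2"], r_s=res["r_s"], r_t=res["r_t"],
                    removal_depth=res["removal_depth"],
                    base_chi2=res["base_chi2"], neg_log10_p=neglogp,
                    fit_r2=r2, admissible=res["admissible"],
                ))
    results = pd.DataFrame([r.__dict__ for r in rows])
    grouped = results.groupby(["pwm_id", "direction"])["neg_log10_p"]
    summary = grouped.agg(mean_neg_log10_p="mean", median_neg_log10_p="median")
    summary["n_significant"] = grouped.apply(lambda s: int((s >= significance).sum()))
    summary["n_comparisons"] = grouped.size()
    summary["consistent"] = summary["n_significant"] >= quorum
    summary = summary.reset_index().sort_values(
        ["direction", "mean_neg_log10_p"], ascending=[True, False]
    ).reset_index(drop=True)
    return results, summary
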
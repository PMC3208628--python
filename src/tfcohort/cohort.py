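"""Target-cohort analysis: permutation detection of regulator-controlled groups.

A gene group (pathway, molecular-function or biological-process set) is
regulated by the profiled transcription factor if its high-target-propensity
members carry systematically larger differential-expression scores — and
larger expression-profile similarity to the regulator — than the group as a
whole.  At each propensity threshold tau the *score increment* is

    delta(tau) = mean(metric | tp >= tau) - mean(metric over the group),

and its interim P-value is the proportion of resampled groups (member metric
values drawn without replacement from the global gene pool, propensities held
fixed) with a larger increment.  Because tau is scanned over a grid, the
final P-value applies a min-P family-wise adjustment: it is the proportion of
resampled groups whose own minimum interim P across thresholds is at least as
small as the observed minimum.  The adjustment is valid for any threshold
grid and errs on the conservative side.

Significant groups are post-processed per the screening workflow: a
*separation threshold* tau* where significance plateaus splits the group,
envelope cutoffs are read off the below-tau* members, and the *target-cohort*
is the set of members above tau* escaping the envelope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .expression import GeneScoreTable

__all__ = [
    "GeneGroup",
    "CohortTestResult",
    "SeparationResult",
    "score_increment",
    "interim_pvalues",
    "minp_final_pvalue",
    "run_target_cohort",
    "storey_qvalues",
    "separation_threshold",
    "envelope_cutoffs",
    "identify_cohort",
    "REFERENCE_CONFIGURATIONS",
]

logger = logging.getLogger(__name__)

METRICS = ("de", "dp", "cov")
DEFAULT_MIN_GROUP_SIZE = 10

#: published screening configurations for the WNT and FGF pathway groups
#: (separation threshold and envelope cutoffs chosen by inspection there)
REFERENCE_CONFIGURATIONS = {
    "wnt": {"separation_threshold": 4.9, "de_cutoff": 0.9,
            "dp_cutoff": 3.2, "cov_cutoff": 0.135},
    "wnt_exploratory": {"separation_threshold": 4.0, "de_cutoff": 0.55,
                        "dp_cutoff": 2.0, "cov_cutoff": 0.1},
    "fgf": {"separation_threshold": 5.1, "de_cutoff": 0.617,
            "dp_cutoff": 1.87, "cov_cutoff": 0.126},
}


@dataclass
class GeneGroup:
    name: str
    members: list[str]
    category: str = "pathway"


@dataclass
class CohortTestResult:
    group: str
    metric: str
    thresholds: np.ndarray
    interim_p: np.ndarray
    min_interim_p: float
    final_p: float
    q: float = float("nan")


@dataclass
class SeparationResult:
    separation_threshold: float
    de_cutoff: float
    dp_cutoff: float
    cov_cutoff: float
    cohort_genes: list[str] = field(default_factory=list)


def score_increment(tp: np.ndarray, metric: np.ndarray, tau: float,
                    baseline: Literal["group", "below"] = "group") -> float:
    """Above-threshold mean minus the baseline mean of the metric.

    The default baseline is the whole-group mean (stable when the below-set
    is tiny); ``baseline="below"`` uses the below-threshold mean instead.
    Zero when the threshold does not split the group (everything — or
    nothing — above tau).
    """
    tp = np.asarray(tp, float)
    metric = np.asarray(metric, float)
    mask = tp >= tau
    if not mask.any() or mask.all():
        return 0.0
    ref = metric.mean() if baseline == "group" else metric[~mask].mean()
    return float(metric[mask].mean() - ref)


def _admissible_thresholds(tp: np.ndarray,
                           thresholds: Sequence[float]) -> np.ndarray:
    """Thresholds leaving at least one member on each side."""
    tp = np.asarray(tp, float)
    keep = [t for t in thresholds
            if (tp >= t).any() and not (tp >= t).all()]
    return np.asarray(keep, float)


def default_thresholds(tp: np.ndarray) -> np.ndarray:
    """Within-group propensity deciles (10%..90%)."""
    return np.unique(np.quantile(np.asarray(tp, float), np.arange(0.1, 1.0, 0.1)))


def _sampled_deltas(group_tp: np.ndarray, pool: np.ndarray,
                    thresholds: np.ndarray, B: int,
                    rng: np.random.Generator,
                    indices: np.ndarray | None = None,
                    baseline: Literal["group", "below"] = "group") -> np.ndarray:
    """B x T matrix of score increments for resampled member values.

    ``indices`` (B x m) optionally fixes which pool entries each sampled
    group receives, so several metrics can share one draw of gene rows.
    """
    m = group_tp.size
    if m > pool.size:
        raise ValueError("group larger than the gene universe")
    if indices is None:
        indices = np.empty((B, m), dtype=np.int64)
        for b in range(B):
            indices[b] = rng.choice(pool.size, size=m, replace=False)
    samples = pool[indices]  # (B, m)
    overall = samples.mean(axis=1)
    deltas = np.zeros((B, thresholds.size))
    for t, tau in enumerate(thresholds):
        mask = group_tp >= tau
        ref = overall if baseline == "group" else samples[:, ~mask].mean(axis=1)
        deltas[:, t] = samples[:, mask].mean(axis=1) - ref
    return deltas


def _interim_from_deltas(obs_delta: np.ndarray,
                         sampled: np.ndarray) -> np.ndarray:
    B = sampled.shape[0]
    count = (sampled >= obs_delta[None, :]).sum(axis=0)
    return (1.0 + count) / (B + 1.0)


def interim_pvalues(group_tp: np.ndarray, group_metric: np.ndarray,
                    pool: np.ndarray, thresholds: Sequence[float],
                    B: int = 1000, seed: int = 0,
                    baseline: Literal["group", "below"] = "group",
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-threshold permutation P-values for one group and metric.

    Returns (admissible thresholds, interim p).  P(tau) is the +1-smoothed
    proportion of resampled groups whose increment at tau reaches the
    observed one.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    taus = _admissible_thresholds(group_tp, thresholds)
    obs = np.array([score_increment(group_tp, group_metric, t, baseline)
                    for t in taus])
    sampled = _sampled_deltas(np.asarray(group_tp, float),
                              np.asarray(pool, float), taus, B, rng,
                              baseline=baseline)
    return taus, _interim_from_deltas(obs, sampled)


def _minp_machinery(obs_delta: np.ndarray, sampled: np.ndarray) -> tuple[
        np.ndarray, float, float]:
    """Interim p, observed min-p and min-P-adjusted final p.

    Each sampled group's own minimum interim p is computed against the full
    sample (leave-self-in), then compared with the observed minimum.
    """
    B = sampled.shape[0]
    interim = _interim_from_deltas(obs_delta, sampled)
    min_obs = float(interim.min())
    # per-column tail counts for every sampled delta, self included
    sample_min_p = np.full(B, np.inf)
    for t in range(sampled.shape[1]):
        col = np.sort(sampled[:, t])
        count_ge = B - np.searchsorted(col, sampled[:, t], side="left")
        p_col = (1.0 + count_ge) / (B + 1.0)
        sample_min_p = np.minimum(sample_min_p, p_col)
    final = (1.0 + (sample_min_p <= min_obs).sum()) / (B + 1.0)
    return interim, min_obs, float(final)


def minp_final_pvalue(group_tp: np.ndarray, group_metric: np.ndarray,
                      pool: np.ndarray, thresholds: Sequence[float],
                      B: int = 1000, seed: int = 0,
                      baseline: Literal["group", "below"] = "group",
                      ) -> CohortTestResult:
    """Full min-P test for one group and metric."""
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    taus = _admissible_thresholds(group_tp, thresholds)
    if taus.size == 0:
        raise ValueError("no admissible propensity thresholds for this group")
    obs = np.array([score_increment(group_tp, group_metric, t, baseline)
                    for t in taus])
    sampled = _sampled_deltas(np.asarray(group_tp, float),
                              np.asarray(pool, float), taus, B, rng,
                              baseline=baseline)
    interim, min_obs, final = _minp_machinery(obs, sampled)
    return CohortTestResult(group="", metric="", thresholds=taus,
                            interim_p=interim, min_interim_p=min_obs,
                            final_p=final)


def run_target_cohort(groups: Mapping[str, Sequence[str]] | Sequence[GeneGroup],
                      score_table: GeneScoreTable, tp: pd.Series,
                      B: int = 1000, seed: int = 0,
                      metrics: Sequence[str] = METRICS,
                      min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
                      null_mode: Literal["values", "rows"] = "values",
                      baseline: Literal["group", "below"] = "group",
                      ) -> tuple[pd.DataFrame, dict[str, dict[str, CohortTestResult]]]:
    """Screen every group with the min-P test for each metric.

    Groups are intersected with the scored gene universe; groups falling
    below ``min_group_size`` are dropped with a log entry.  Thresholds are
    the within-group propensity deciles.  ``null_mode="rows"`` draws whole
    gene rows per resample (shared across metrics, preserving inter-metric
    correlation) instead of independent per-metric value pools.

    Returns a results frame (one row per group, ``final_p_<metric>``,
    ``q_<metric>``, ``min_interim_p_<metric>`` columns) plus the per-group
    detailed results.
    """
    if isinstance(groups, Mapping):
        groups = [GeneGroup(name, list(members)) for name, members in groups.items()]
    if isinstance(tp, pd.DataFrame):
        tp = tp["tp"]
    universe = score_table.genes.intersection(tp.index)
    pools = {
        "de": score_table.de_score.loc[universe].to_numpy(float),
        "dp": score_table.dp.loc[universe].to_numpy(float),
        "cov": score_table.cov.loc[universe].to_numpy(float),
    }
    gene_pos = {g: i for i, g in enumerate(universe)}
    ss = np.random.SeedSequence(seed)
    details: dict[str, dict[str, CohortTestResult]] = {}
    rows = []
    for group, child in zip(groups, ss.spawn(len(groups))):
        members = [g for g in group.members if g in gene_pos]
        if len(members) < min_group_size:
            logger.info("group %s skipped: %d scored members < %d",
                        group.name, len(members), min_group_size)
            continue
        idx = np.array([gene_pos[g] for g in members])
        group_tp = tp.loc[universe].to_numpy(float)[idx]
        taus = _admissible_thresholds(group_tp, default_thresholds(group_tp))
        if taus.size == 0:
            logger.info("group %s skipped: no admissible thresholds", group.name)
            continue
        rng = np.random.default_rng(child)
        shared_indices = None
        if null_mode == "rows":
            shared_indices = np.empty((B, len(members)), dtype=np.int64)
            for b in range(B):
                shared_indices[b] = rng.choice(len(universe), size=len(members),
                                               replace=False)
        row: dict = {"group": group.name, "category": group.category,
                     "n_members": len(members)}
        details[group.name] = {}
        for metric in metrics:
            pool = pools[metric]
            vals = pool[idx]
            obs = np.array([score_increment(group_tp, vals, t, baseline)
                            for t in taus])
            sampled = _sampled_deltas(group_tp, pool, taus, B, rng,
                                      indices=shared_indices,
                                      baseline=baseline)
            interim, min_obs, final = _minp_machinery(obs, sampled)
            res = CohortTestResult(group=group.name, metric=metric,
                                   thresholds=taus, interim_p=interim,
                                   min_interim_p=min_obs, final_p=final)
            details[group.name][metric] = res
            row[f"final_p_{metric}"] = final
            row[f"min_interim_p_{metric}"] = min_obs
        rows.append(row)
    results = pd.DataFrame(rows)
    if len(results):
        results = results.set_index("group")
        for metric in metrics:
            q = storey_qvalues(results[f"final_p_{metric}"].to_numpy())
            results[f"q_{metric}"] = q
            for name in results.index:
                details[name][metric].q = float(results.loc[name, f"q_{metric}"])
    return results, details


def storey_qvalues(pvals: np.ndarray,
                   lambda_grid: np.ndarray | None = None,
                   pi0: float | None = None) -> np.ndarray:
    """False-discovery-rate q-values with smoother-based pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated over the
    lambda grid (default 0.05..0.95) and a cubic smoothing spline evaluated
    at the largest lambda gives the estimate of the null proportion.  With
    fewer than 10 P-values pi0 is fixed at 1 with a warning.  q_i is the
    running minimum of pi0 * m * p / rank, capped at 1 — monotone
    non-decreasing in p.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        if m < 10:
            warnings.warn("fewer than 10 p-values; pi0 fixed at 1", RuntimeWarning)
            pi0 = 1.0
        else:
            lam = (np.arange(0.05, 0.96, 0.05) if lambda_grid is None
                   else np.asarray(lambda_grid, float))
            pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
            spline = UnivariateSpline(lam, pi0_lam, k=3)
            pi0 = float(spline(lam.max()))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum(np.minimum.accumulate(q[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def separation_threshold(profiles: Mapping[str, tuple[np.ndarray, np.ndarray]],
                         tolerance: float = 0.1,
                         manual_override: float | None = None) -> float | None:
    """Propensity threshold where group significance plateaus.

    ``profiles`` maps metric name to (thresholds, interim p).  The
    per-threshold average of -log10 interim p across metrics is computed;
    the separation threshold is the largest tau whose profile value lies
    within ``tolerance`` of the maximum — the onset of the plateau reached
    as tau decreases.  A manual override always wins (thresholds were chosen
    by inspection in the original screening workflow).  Returns None, with a
    warning, when the profile is flat.
    """
    if manual_override is not None:
        return float(manual_override)
    taus = None
    acc = None
    for metric, (t, p) in profiles.items():
        t = np.asarray(t, float)
        if taus is None:
            taus = t
            acc = np.zeros_like(t)
        elif t.shape != taus.shape or not np.allclose(t, taus):
            raise ValueError("metric profiles use different threshold grids")
        acc = acc + (-np.log10(np.asarray(p, float)))
    if taus is None or taus.size == 0:
        raise ValueError("no interim profiles supplied")
    profile = acc / len(profiles)
    peak = profile.max()
    if np.isclose(peak, profile.min()):
        warnings.warn("flat significance profile; separation threshold undefined",
                      RuntimeWarning)
        return None
    ok = profile >= peak - tolerance * abs(peak)
    return float(taus[ok].max())


def _iqr_filter(values: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(values, [25, 75])
    return values[values <= q3 + 1.5 * (q3 - q1)]


def envelope_cutoffs(below_de: np.ndarray, below_dp: np.ndarray,
                     below_cov: np.ndarray,
                     outlier_rule: Literal["iqr", "none"] = "iqr",
                     ) -> tuple[float, float, float]:
    """Score cutoffs from the members below the separation threshold.

    Each cutoff is the maximum over the below-threshold members after
    excluding outliers (values above Q3 + 1.5 IQR); similarity cutoffs use
    absolute values.  Falls back to the unfiltered maximum with a warning if
    the rule rejects everything.
    """
    out = []
    for vals in (np.asarray(below_de, float),
                 np.abs(np.asarray(below_dp, float)),
                 np.abs(np.asarray(below_cov, float))):
        if vals.size < 2:
            raise ValueError("need >=2 members below the separation threshold")
        kept = _iqr_filter(vals) if outlier_rule == "iqr" else vals
        if kept.size == 0:
            warnings.warn("all below-threshold members flagged as outliers; "
                          "using unfiltered maximum", RuntimeWarning)
            kept = vals
        out.append(float(kept.max()))
    return tuple(out)  # type: ignore[return-value]


def identify_cohort(members: Sequence[str], tp: pd.Series,
                    score_table: GeneScoreTable, tau_star: float,
                    de_cutoff: float, dp_cutoff: float,
                    cov_cutoff: float) -> list[str]:
    """Members above tau* escaping the envelope: the putative target-cohort.

    A member qualifies with tp >= tau*, de > de_cutoff and |dp| > dp_cutoff
    or |cov| > cov_cutoff.  Output order follows sorted gene IDs, so it is
    invariant to input ordering.
    """
    cohort = []
    for g in sorted(set(members)):
        if tp.loc[g] < tau_star:
            continue
        if score_table.de_score.loc[g] <= de_cutoff:
            continue
        if (abs(score_table.dp.loc[g]) > dp_cutoff
                or abs(score_table.cov.loc[g]) > cov_cutoff):
            cohort.append(g)
    return cohort


def separation_analysis(group: GeneGroup, score_table: GeneScoreTable,
                        tp: pd.Series,
                        detail: Mapping[str, CohortTestResult],
                        tolerance: float = 0.1,
                        manual_override: float | None = None,
                        ) -> SeparationResult | None:
    """Separation threshold, envelope cutoffs and cohort list for one group."""
    profiles = {m: (r.thresholds, r.interim_p) for m, r in detail.items()}
    tau = separation_threshold(profiles, tolerance=tolerance,
                               manual_override=manual_override)
    if tau is None:
        return None
    members = [g for g in group.members if g in tp.index]
    member_tp = tp.loc[members]
    below = member_tp.index[member_tp < tau]
    de_c, dp_c, cov_c = envelope_cutoffs(
        score_table.de_score.loc[below].to_numpy(),
        score_table.dp.loc[below].to_numpy(),
        score_table.cov.loc[below].to_numpy(),
    )
    cohort = identify_cohort(members, tp, score_table, tau, de_c, dp_c, cov_c)
    return SeparationResult(tau, de_c, dp_c, cov_c, cohort)
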
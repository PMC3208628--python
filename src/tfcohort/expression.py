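"""Differential-expression scoring across two-class comparisons.

Each comparison contrasts a case class (e.g. pluripotent stem cell samples)
against a control class (e.g. fibroblasts).  Per gene and comparison a
moderated two-sample statistic d = (mean_case - mean_control) / (s + s0) is
computed, where s is the pooled standard error of the mean difference and s0
a small positive "fudge" constant that stabilises genes with tiny variance.
The per-comparison d values are standardised to mean 0 / sd 1 (z), and the
pooled differential-expression (DE) score of a gene is the mean of |z| across
comparisons.

Similarity of a gene's z-profile with a designated regulator gene is measured
two ways: the raw dot product across comparisons, and the population
covariance.  Both are signed — concordant regulation yields positive values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionComparison",
    "GeneScoreTable",
    "filter_probes",
    "sam_statistic",
    "scale_scores",
    "pooled_de_score",
    "similarity_dot",
    "similarity_cov",
    "group_similarity",
    "rank_profile",
    "build_score_table",
    "read_expression_tsv",
]

logger = logging.getLogger(__name__)

#: probe-set ID suffixes dropped before analysis (cross-hybridising /
#: non-specific probe classes on Affymetrix arrays)
EXCLUDED_PROBE_SUFFIXES = ("_a_at", "_s_at", "_x_at")


@dataclass
class ExpressionComparison:
    """One two-class expression matrix (genes x samples)."""

    matrix: pd.DataFrame
    class_labels: Sequence[str]  # per-sample, "case" or "control"
    comparison_id: str

    def __post_init__(self) -> None:
        labels = list(self.class_labels)
        if len(labels) != self.matrix.shape[1]:
            raise ValueError(
                f"{self.comparison_id}: {len(labels)} class labels for "
                f"{self.matrix.shape[1]} samples"
            )
        bad = set(labels) - {"case", "control"}
        if bad:
            raise ValueError(f"{self.comparison_id}: unknown class labels {bad}")
        if labels.count("case") < 2 or labels.count("control") < 2:
            raise ValueError(f"{self.comparison_id}: need >=2 samples per class")
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()][:5].tolist()
            raise ValueError(f"{self.comparison_id}: duplicate gene IDs, e.g. {dups}")
        self.class_labels = labels

    @property
    def case(self) -> pd.DataFrame:
        mask = [lab == "case" for lab in self.class_labels]
        return self.matrix.loc[:, mask]

    @property
    def control(self) -> pd.DataFrame:
        mask = [lab == "control" for lab in self.class_labels]
        return self.matrix.loc[:, mask]


def read_expression_tsv(path, comparison_id: str | None = None) -> ExpressionComparison:
    """Read a genes x samples TSV whose column names start with case_/control_."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    labels = []
    for col in df.columns:
        if col.startswith("case"):
            labels.append("case")
        elif col.startswith("control"):
            labels.append("control")
        else:
            raise ValueError(f"{path}: column {col!r} has no case_/control_ prefix")
    cid = comparison_id or str(path)
    return ExpressionComparison(df, labels, cid)


def filter_probes(gene_ids: Iterable[str]) -> list[str]:
    """Drop probe-set IDs ending with _a_at, _s_at or _x_at; keep order."""
    return [g for g in gene_ids if not g.endswith(EXCLUDED_PROBE_SUFFIXES)]


def _pooled_se(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Pooled standard error of the mean difference, per gene (rows)."""
    n1, n2 = case.shape[1], control.shape[1]
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + control.var(axis=1, ddof=1) * (n2 - 1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))


def _tusher_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Coefficient-of-variation-minimising fudge constant.

    Candidates are the percentiles of s (0, 5, ..., 100).  For each candidate
    the genes are cut into 100 s-quantile bins; the candidate minimising the
    coefficient of variation of the within-bin MADs of d = r/(s+s0) wins.
    """
    candidates = np.percentile(s, np.arange(0, 101, 5))
    order = np.argsort(s, kind="mergesort")
    bins = np.array_split(order, 100)
    best, best_cv = candidates[0], np.inf
    for s0 in candidates:
        if s0 < 0 or not np.isfinite(s0):
            continue
        d = r / (s + s0)
        mads = np.array([stats.median_abs_deviation(d[b], scale="normal")
                         for b in bins if b.size])
        mean = mads.mean()
        if mean == 0:
            continue
        cv = mads.std(ddof=0) / mean
        if cv < best_cv:
            best_cv, best = cv, s0
    return float(best)


def sam_statistic(comparison: ExpressionComparison,
                  s0_rule: Literal["median", "tusher"] | float = "median") -> pd.Series:
    """Moderated two-sample d statistic per gene.

    d = (mean_case - mean_control) / (s + s0) with s the pooled standard
    error.  ``s0_rule`` may be "median" (median of s; default), "tusher"
    (coefficient-of-variation minimiser) or an explicit non-negative float.
    """
    case = comparison.case.to_numpy(float)
    control = comparison.control.to_numpy(float)
    r = case.mean(axis=1) - control.mean(axis=1)
    s = _pooled_se(case, control)
    if isinstance(s0_rule, str):
        if s0_rule == "median":
            s0 = float(np.median(s))
        elif s0_rule == "tusher":
            s0 = _tusher_s0(r, s)
        else:
            raise ValueError(f"unknown s0 rule {s0_rule!r}")
    else:
        s0 = float(s0_rule)
        if s0 < 0:
            raise ValueError("s0 must be non-negative")
    denom = s + s0
    if np.any(denom == 0):
        n_bad = int(np.sum(denom == 0))
        raise ValueError(
            f"{comparison.comparison_id}: {n_bad} gene(s) with zero variance in "
            "both classes and s0=0; supply a positive s0"
        )
    return pd.Series(r / denom, index=comparison.matrix.index, name="d")


def scale_scores(d: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Standardise to mean 0, sd 1 (population moments)."""
    arr = np.asarray(d, dtype=float)
    if arr.size < 2:
        raise ValueError("need >=2 genes to scale scores")
    sd = arr.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot scale scores with zero standard deviation")
    z = (arr - arr.mean()) / sd
    if isinstance(d, pd.Series):
        return pd.Series(z, index=d.index, name="z")
    return z


def pooled_de_score(z: pd.DataFrame) -> pd.Series:
    """Mean |z| across comparisons (columns) per gene."""
    if z.shape[1] < 1:
        raise ValueError("need >=1 comparison")
    return z.abs().mean(axis=1).rename("de_score")


def similarity_dot(a: np.ndarray, b: np.ndarray) -> float:
    """Raw dot product of two z-profiles over comparisons."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    return float(a @ b)


def similarity_cov(a: np.ndarray, b: np.ndarray) -> float:
    """Population covariance of two z-profiles over comparisons."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need >=2 comparisons for covariance")
    return float(np.mean((a - a.mean()) * (b - b.mean())))


@dataclass
class GeneScoreTable:
    """Per-gene scores pooled over comparisons.

    Attributes
    ----------
    z : genes x comparisons DataFrame of scaled d statistics.
    de_score : mean |z| per gene.
    dp, cov : dot-product / covariance similarity with the regulator gene.
    regulator_gene : the designated regulator's gene ID.
    """

    z: pd.DataFrame
    de_score: pd.Series
    dp: pd.Series
    cov: pd.Series
    regulator_gene: str

    @property
    def n_comparisons(self) -> int:
        return self.z.shape[1]

    @property
    def genes(self) -> pd.Index:
        return self.z.index

    def to_frame(self) -> pd.DataFrame:
        df = self.z.copy()
        df.columns = [f"z_{c}" for c in df.columns]
        df["de_score"] = self.de_score
        df["dp"] = self.dp
        df["cov"] = self.cov
        return df

    def to_tsv(self, path, extra_comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for comment in extra_comments:
                fh.write(f"# {comment}\n")
            fh.write(f"# regulator_gene={self.regulator_gene}\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="gene",
                                   lineterminator="\n")

    @classmethod
    def from_tsv(cls, path) -> "GeneScoreTable":
        regulator = None
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if line.startswith("# regulator_gene="):
                    regulator = line.strip().split("=", 1)[1]
        df = pd.read_csv(path, sep="\t", index_col="gene", comment="#")
        zcols = [c for c in df.columns if c.startswith("z_")]
        z = df[zcols].copy()
        z.columns = [c[2:] for c in zcols]
        return cls(z, df["de_score"], df["dp"], df["cov"], regulator or "")


def build_score_table(comparisons: Sequence[ExpressionComparison],
                      regulator_gene: str,
                      s0_rule: Literal["median", "tusher"] | float = "median",
                      apply_probe_filter: bool = True) -> GeneScoreTable:
    """Score every comparison, standardise, pool, and attach similarities.

    The gene universe is the intersection of genes present in all comparisons
    (after the probe-suffix filter); genes missing anywhere are dropped with a
    logged count.
    """
    if not comparisons:
        raise ValueError("need >=1 comparison")
    universes = []
    for comp in comparisons:
        ids = list(comp.matrix.index)
        if apply_probe_filter:
            ids = filter_probes(ids)
        universes.append(ids)
    common = set(universes[0])
    for u in universes[1:]:
        common &= set(u)
    genes = [g for g in universes[0] if g in common]
    n_drop = sum(len(u) for u in universes) - len(genes) * len(universes)
    if n_drop:
        logger.info("dropped %d gene entries absent from some comparison", n_drop)
    if regulator_gene not in common:
        raise ValueError(f"regulator gene {regulator_gene!r} not in shared universe")

    zcols = {}
    for comp in comparisons:
        d = sam_statistic(comp, s0_rule=s0_rule).loc[genes]
        zcols[comp.comparison_id] = scale_scores(d)
    z = pd.DataFrame(zcols, index=pd.Index(genes, name="gene"))
    de = pooled_de_score(z)
    a = z.loc[regulator_gene].to_numpy()
    zmat = z.to_numpy()
    dp = pd.Series(zmat @ a, index=z.index, name="dp")
    ac = a - a.mean()
    bc = zmat - zmat.mean(axis=1, keepdims=True)
    cov = pd.Series(bc @ ac / z.shape[1], index=z.index, name="cov")
    return GeneScoreTable(z, de, dp, cov, regulator_gene)


def group_similarity(table: GeneScoreTable, genes: Iterable[str],
                     metric: Literal["de", "dp", "cov"]) -> float:
    """Unweighted mean of a per-gene metric over a gene group."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene group")
    series = {"de": table.de_score, "dp": table.dp, "cov": table.cov}[metric]
    missing = [g for g in genes if g not in series.index]
    if missing:
        raise ValueError(f"unknown gene(s) in group: {missing[:5]}")
    return float(series.loc[genes].mean())


def rank_profile(values: pd.Series, propensity: pd.Series,
                 window: int = 250) -> tuple[pd.DataFrame, float, float]:
    """Moving average of ``values`` over genes sorted by descending propensity.

    Returns (profile, rho, p): the profile DataFrame with columns ``tp_rank``
    and ``moving_avg`` (NaN until the window fills), plus the Spearman
    correlation between propensity and the value with its two-sided p-value.
    """
    if window < 2:
        raise ValueError("window must be >=2")
    common = values.index.intersection(propensity.index)
    if window > len(common):
        raise ValueError(f"window {window} exceeds {len(common)} genes")
    v = values.loc[common]
    tp = propensity.loc[common]
    order = pd.DataFrame({"tp": tp, "v": v}).sort_values(
        ["tp"], ascending=False, kind="mergesort"
    )
    profile = pd.DataFrame({
        "tp_rank": np.arange(1, len(order) + 1),
        "moving_avg": order["v"].rolling(window).mean().to_numpy(),
    }, index=order.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(tp.to_numpy(), v.to_numpy())
    return profile, float(rho), float(p)
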
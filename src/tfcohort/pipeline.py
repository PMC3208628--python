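"""End-to-end orchestration of the simulate / screen / cohort stages.

Every stage reads and writes plain-text artifacts (FASTA promoters, TRANSFAC
matrices, TSV expression and score tables, GMT groups), so any stage can be
fed user data instead of the synthetic generator's output.  All stochastic
stages derive their streams from the single configured seed, and every output
table carries a header naming the producing version and the configuration
checksum — two runs with identical configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, io as tfio
from .cohort import run_target_cohort, separation_analysis, GeneGroup
from .expression import GeneScoreTable, build_score_table, read_expression_tsv
from .motif import PromoterSet, build_propensity_table, read_pwm_transfac, \
    write_pwm_transfac
from .synthetic import SyntheticConfig, generate_dataset
from .tfa import tfa_screen

logger = logging.getLogger(__name__)

DEFAULT_SCREEN = {
    "n_perm": 10000, "min_expected": 10.0, "grid_step": None, "n_depths": 5,
    "significance": 2.0, "quorum": 6, "mss_cutoff": 0.75, "css_cutoff": 0.90,
    "s0_rule": "median",
}
DEFAULT_COHORT = {
    "B": 1000, "min_group_size": 10, "null_mode": "values",
    "baseline": "group", "q_cutoff": 0.267, "tolerance": 0.1,
    "manual_separation_threshold": None,
}
QUICK_OVERRIDES = {"n_perm": 500, "B": 200}


@dataclasses.dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    regulator_gene: str | None = None
    regulator_pwm: str | None = None
    synthetic: dict = dataclasses.field(default_factory=dict)
    screen: dict = dataclasses.field(default_factory=dict)
    cohort: dict = dataclasses.field(default_factory=dict)
    paths: dict = dataclasses.field(default_factory=dict)
    resume: bool = False
    quick: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.screen = {**DEFAULT_SCREEN, **self.screen}
        self.cohort = {**DEFAULT_COHORT, **self.cohort}
        if self.quick:
            self.screen["n_perm"] = QUICK_OVERRIDES["n_perm"]
            self.cohort["B"] = QUICK_OVERRIDES["B"]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def checksum(self) -> str:
        """Digest of the scientific configuration (not the output location)."""
        payload = dataclasses.asdict(self)
        for key in ("outdir", "resume", "quick"):
            payload.pop(key, None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header_comments(self) -> list[str]:
        return [f"tfcohort {__version__} config_sha256={self.checksum()}"]


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig,
                 index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        for comment in cfg.header_comments():
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label, lineterminator="\n")


def run_simulate(cfg: PipelineConfig) -> dict[str, Any]:
    """Generate and write the synthetic dataset plus truth files."""
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    syn = SyntheticConfig(**{**cfg.synthetic, "seed": cfg.seed})
    expected = [out / f"expr_comp{i + 1}.tsv" for i in range(syn.n_comparisons)]
    artifacts = [out / "promoters.fasta", out / "pwms.transfac",
                 out / "groups.gmt", out / "truth_genes.tsv",
                 out / "truth_promoters.tsv", out / "truth_groups.tsv",
                 *expected]
    if cfg.resume and all(p.exists() for p in artifacts):
        logger.info("simulate: artifacts present, resuming")
        return {"paths": artifacts, "config": syn}
    ds = generate_dataset(syn)
    ds.promoters.to_fasta(out / "promoters.fasta")
    write_pwm_transfac([ds.regulator_pwm, *ds.decoy_pwms], out / "pwms.transfac")
    for comp, path in zip(ds.comparisons, expected):
        with open(path, "w") as fh:
            for comment in cfg.header_comments():
                fh.write(f"# {comment}\n")
            comp.matrix.to_csv(fh, sep="\t", index_label="gene",
                               lineterminator="\n")
    from .synthetic import _CATEGORIES
    descriptions = {name: _CATEGORIES[i % len(_CATEGORIES)]
                    for i, name in enumerate(ds.groups)}
    tfio.write_gmt(ds.groups, out / "groups.gmt", descriptions=descriptions)
    ds.truth.to_tsv(out / "truth_genes.tsv", out / "truth_promoters.tsv",
                    out / "truth_groups.tsv")
    tfio.write_manifest(artifacts, out / "manifest.tsv")
    logger.info("simulate: wrote %d artifacts to %s", len(artifacts), out)
    return {"paths": artifacts, "config": syn, "dataset": ds}


def _resolve_inputs(cfg: PipelineConfig) -> dict[str, Any]:
    out = cfg.outdir
    expr_paths = cfg.paths.get("expression") or sorted(out.glob("expr_comp*.tsv"))
    if not expr_paths:
        raise FileNotFoundError("no expression TSVs found; run simulate first "
                                "or set paths.expression")
    promoters = cfg.paths.get("promoters", out / "promoters.fasta")
    pwms = cfg.paths.get("pwms", out / "pwms.transfac")
    groups = cfg.paths.get("groups", out / "groups.gmt")
    return {"expression": [Path(p) for p in expr_paths],
            "promoters": Path(promoters), "pwms": Path(pwms),
            "groups": Path(groups)}


def run_screen(cfg: PipelineConfig) -> dict[str, Any]:
    """Score expression, scan promoters, and run the TFA screen."""
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    inputs = _resolve_inputs(cfg)
    results_path = out / "tfa_results.tsv"
    summary_path = out / "tfa_summary.tsv"
    score_path = out / "score_table.tsv"
    tp_path = out / "propensity.tsv"
    if cfg.resume and all(p.exists() for p in
                          (results_path, summary_path, score_path, tp_path)):
        logger.info("screen: outputs present, resuming")
        return {"results": pd.read_csv(results_path, sep="\t", comment="#"),
                "summary": pd.read_csv(summary_path, sep="\t", comment="#")}

    comparisons = [read_expression_tsv(p, comparison_id=p.stem.replace("expr_", ""))
                   for p in inputs["expression"]]
    regulator = cfg.regulator_gene
    if regulator is None:
        truth_path = out / "truth_genes.tsv"
        if truth_path.exists():
            truth = pd.read_csv(truth_path, sep="\t", index_col="gene")
            regulator = truth.index[truth["is_regulator"] == 1][0]
        else:
            raise ValueError("regulator_gene must be configured for user data")
    try:
        table = build_score_table(comparisons, regulator,
                                  s0_rule=cfg.screen["s0_rule"])
    except ValueError as exc:
        raise RuntimeError(f"screen stage failed in expression scoring: {exc}")

    promoters = PromoterSet.from_fasta(inputs["promoters"])
    pwms = read_pwm_transfac(inputs["pwms"],
                             mss_cutoff=cfg.screen["mss_cutoff"],
                             css_cutoff=cfg.screen["css_cutoff"])
    tp_tables = {}
    tp_rows = []
    for pwm in pwms:
        tp_df = build_propensity_table(promoters, pwm)
        tp_tables[pwm.id] = tp_df["tp"]
        block = tp_df.reset_index()
        block.insert(0, "pwm_id", pwm.id)
        block["background_density"] = tp_df.attrs["background_density"]
        tp_rows.append(block)
    results, summary = tfa_screen(
        table, tp_tables,
        n_perm=cfg.screen["n_perm"], seed=cfg.seed,
        min_expected=cfg.screen["min_expected"],
        grid_step=cfg.screen["grid_step"], n_depths=cfg.screen["n_depths"],
        significance=cfg.screen["significance"], quorum=cfg.screen["quorum"],
    )
    table.to_tsv(score_path, extra_comments=cfg.header_comments())
    _write_table(pd.concat(tp_rows, ignore_index=True), tp_path, cfg)
    _write_table(results, results_path, cfg)
    _write_table(summary, summary_path, cfg)
    logger.info("screen: %d cells screened, summary at %s", len(results),
                summary_path)
    return {"results": results, "summary": summary, "score_table": table,
            "tp_tables": tp_tables}


def run_cohort(cfg: PipelineConfig) -> dict[str, Any]:
    """Min-P target-cohort screen for the configured regulator PWM."""
    out = cfg.outdir
    inputs = _resolve_inputs(cfg)
    score_path = out / "score_table.tsv"
    tp_path = out / "propensity.tsv"
    if not (score_path.exists() and tp_path.exists()):
        run_screen(cfg)
    table = GeneScoreTable.from_tsv(score_path)
    tp_all = pd.read_csv(tp_path, sep="\t", comment="#")
    pwm_id = cfg.regulator_pwm or tp_all["pwm_id"].iloc[0]
    tp = tp_all[tp_all["pwm_id"] == pwm_id].set_index("gene")["tp"]
    if tp.empty:
        raise ValueError(f"regulator PWM {pwm_id!r} absent from propensity table")
    groups_raw = tfio.read_gmt(inputs["groups"]) if inputs["groups"].exists() else {}
    if not groups_raw:
        logger.warning("empty group file; writing empty results table")
        empty = pd.DataFrame()
        _write_table(empty, out / "cohort_results.tsv", cfg)
        return {"results": empty, "details": {}}
    results, details = run_target_cohort(
        groups_raw, table, tp, B=cfg.cohort["B"], seed=cfg.seed,
        min_group_size=cfg.cohort["min_group_size"],
        null_mode=cfg.cohort["null_mode"],
        baseline=cfg.cohort["baseline"],
    )
    _write_table(results, out / "cohort_results.tsv", cfg, index_label="group")
    profile_rows = []
    for name, metrics in details.items():
        for metric, res in metrics.items():
            for tau, p in zip(res.thresholds, res.interim_p):
                profile_rows.append({"group": name, "metric": metric,
                                     "threshold": tau, "interim_p": p})
    _write_table(pd.DataFrame(profile_rows), out / "cohort_profiles.tsv", cfg)
    # separation diagnostics + cohort gene lists for significant groups
    sep_rows = []
    q_cut = cfg.cohort["q_cutoff"]
    for name, metrics in details.items():
        if min(r.q for r in metrics.values()) > q_cut:
            continue
        group = GeneGroup(name, groups_raw[name])
        try:
            sep = separation_analysis(group, table, tp, metrics,
                                      tolerance=cfg.cohort["tolerance"],
                                      manual_override=cfg.cohort[
                                          "manual_separation_threshold"])
        except ValueError as exc:
            logger.info("group %s: separation diagnostics unavailable (%s)",
                        name, exc)
            continue
        if sep is None:
            continue
        sep_rows.append({
            "group": name, "separation_threshold": sep.separation_threshold,
            "de_cutoff": sep.de_cutoff, "dp_cutoff": sep.dp_cutoff,
            "cov_cutoff": sep.cov_cutoff,
            "cohort_genes": ",".join(sep.cohort_genes),
        })
    _write_table(pd.DataFrame(sep_rows), out / "cohort_genes.tsv", cfg)
    logger.info("cohort: %d groups tested, %d with separation diagnostics",
                len(results), len(sep_rows))
    return {"results": results, "details": details}


def run_all(cfg: PipelineConfig) -> dict[str, Any]:
    run_simulate(cfg)
    screen = run_screen(cfg)
    cohort = run_cohort(cfg)
    return {"screen": screen, "cohort": cohort}
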
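"""Synthetic promoters, expression matrices and gene groups with planted truth.

The generator emulates the structure of a multi-comparison pluripotent-vs-
fibroblast microarray study: a minority of *target* genes carry elevated
binding-site density for a planted regulator motif in their promoters and are
up-shifted in the case class of every comparison, proportionally to their
site density.  Gene groups are emitted with controlled target enrichment so
that every downstream stage — scoring, scanning, the activity screen, and
the cohort test — can be validated against known ground truth.

Background sequence is i.i.d. uniform ACGT; planted sites are exact draws
from the motif's per-position base distribution, placed non-overlapping with
a uniformly drawn strand.  Expression noise is Gaussian; the target up-shift
is deterministic given a gene's planted site density, so expression-profile
similarity with the regulator gene is positive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionComparison
from .motif import BASES, PWM, Promoter, PromoterSet

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "make_regulator_pwm",
    "generate_promoters",
    "generate_expression",
    "generate_gene_groups",
    "generate_dataset",
]

#: degenerate consensus of the planted regulator motif (S = C or G, N = any)
REGULATOR_PATTERN = "NTTTSSCGSS"

_PATTERN_COUNTS = {
    # counts out of 40 pseudo-sites per position, order A C G T
    "N": (10, 10, 10, 10),
    "T": (2, 2, 2, 34),
    "C": (2, 34, 2, 2),
    "G": (2, 2, 34, 2),
    "S": (3, 17, 17, 3),
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Defaults describe a desk-scale screen: 5,000 genes of which 200 are
    planted regulator targets with five-fold background site density, seven
    two-class comparisons with three replicates per class, and a hundred
    50-gene groups of which five are enriched to 40% targets.
    """

    n_genes: int = 5000
    n_comparisons: int = 7
    samples_per_class: int = 3
    promoter_len: int = 600
    alt_promoters_min: int = 1
    alt_promoters_max: int = 3
    n_targets: int = 200
    site_density_ratio: float = 5.0
    background_site_rate: float = 0.002  # sites per base
    effect_size: float = 3.0  # in noise-sd units
    noise_sd: float = 1.0
    n_groups: int = 100
    group_size: int = 50
    n_enriched_groups: int = 5
    enriched_group_target_fraction: float = 0.4
    n_decoys: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_targets <= self.n_genes):
            raise ValueError("n_targets must lie in [0, n_genes]")
        if self.site_density_ratio < 1:
            raise ValueError("site_density_ratio must be >= 1")
        if not 0 <= self.enriched_group_target_fraction <= 1:
            raise ValueError("enriched_group_target_fraction must lie in [0, 1]")
        for name in ("n_genes", "n_comparisons", "samples_per_class",
                     "promoter_len", "alt_promoters_min", "alt_promoters_max",
                     "group_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_site_rate < 0 or self.noise_sd <= 0:
            raise ValueError("rates must be non-negative and noise_sd positive")
        if self.alt_promoters_min > self.alt_promoters_max:
            raise ValueError("alt promoter range inverted")
        if self.n_enriched_groups > self.n_groups:
            raise ValueError("n_enriched_groups exceeds n_groups")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the synthetic artifacts."""

    target_flags: pd.Series  # bool per gene
    planted_site_counts: pd.Series  # int per promoter ID
    regulator_gene: str
    enriched_group_ids: set[str] = field(default_factory=set)

    def planted_gene_density(self, promoter_len: int) -> pd.Series:
        """Planted sites per base per gene (averaged over its promoters)."""
        gene_of = self.planted_site_counts.index.str.rsplit("_p", n=1).str[0]
        per_gene = self.planted_site_counts.groupby(gene_of)
        dens = per_gene.sum() / (per_gene.count() * promoter_len)
        return dens.reindex(self.target_flags.index).fillna(0.0)

    def to_tsv(self, gene_path, promoter_path, group_path) -> None:
        genes = pd.DataFrame({
            "is_target": self.target_flags.astype(int),
            "is_regulator": (self.target_flags.index == self.regulator_gene).astype(int),
        })
        genes.to_csv(gene_path, sep="\t", index_label="gene")
        self.planted_site_counts.rename("planted_sites").to_csv(
            promoter_path, sep="\t", index_label="promoter"
        )
        with open(group_path, "w") as fh:
            fh.write("group\tis_enriched\n")
            for name in sorted(self.enriched_group_ids):
                fh.write(f"{name}\t1\n")


def make_regulator_pwm(seed: int, n_decoys: int = 10) -> tuple[PWM, list[PWM]]:
    """The planted 10-position regulator matrix plus column-shuffled decoys.

    The regulator's consensus follows the degenerate pattern NTTTSSCGSS
    (S = C/G); decoys permute the position order under the seeded stream, so
    they share base composition (hence background hit rate) but not the
    planted word.
    """
    counts = np.array([_PATTERN_COUNTS[c] for c in REGULATOR_PATTERN], dtype=float)
    regulator = PWM(id="M_SYNREG_01", counts=counts)
    rng = np.random.default_rng(seed)
    decoys = []
    for k in range(n_decoys):
        perm = rng.permutation(counts.shape[0])
        while np.array_equal(perm, np.arange(counts.shape[0])):
            perm = rng.permutation(counts.shape[0])
        decoys.append(PWM(id=f"M_DECOY_{k + 1:02d}", counts=counts[perm]))
    return regulator, decoys


def _sample_site(rng: np.random.Generator, pwm: PWM) -> np.ndarray:
    """Draw one site (int codes) from the PWM's per-position base distribution."""
    u = rng.random(pwm.length)
    cum = np.cumsum(pwm.freqs, axis=1)
    return (u[:, None] < cum).argmax(axis=1).astype(np.int8)


_CODE_TO_BASE = np.frombuffer("ACGT".encode(), dtype=np.uint8)


def generate_promoters(config: SyntheticConfig,
                       pwm: PWM) -> tuple[PromoterSet, SyntheticTruth]:
    """Uniform-background promoters with Poisson-planted motif occurrences.

    Targets receive sites at ``site_density_ratio x background_site_rate``
    per base, non-targets at the background rate.  Sites are placed at
    non-overlapping uniform positions on a uniformly drawn strand; placement
    is retried up to 100 times before an overflow error naming the promoter.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = config.gene_ids()
    regulator_gene = genes[0]
    candidates = np.array(genes[1:])
    target_genes = set(
        rng.choice(candidates, size=config.n_targets, replace=False)
    ) if config.n_targets else set()
    target_flags = pd.Series(
        [g in target_genes for g in genes], index=pd.Index(genes, name="gene")
    )

    L = pwm.length
    promoters: list[Promoter] = []
    counts: dict[str, int] = {}
    comp = np.array([3, 2, 1, 0], dtype=np.int8)
    for gene in genes:
        n_prom = int(rng.integers(config.alt_promoters_min,
                                  config.alt_promoters_max + 1))
        rate = config.background_site_rate * (
            config.site_density_ratio if gene in target_genes else 1.0
        )
        for j in range(1, n_prom + 1):
            pid = f"{gene}_p{j}"
            codes = rng.integers(0, 4, size=config.promoter_len).astype(np.int8)
            n_sites = int(rng.poisson(rate * config.promoter_len))
            occupied = np.zeros(config.promoter_len, dtype=bool)
            for _ in range(n_sites):
                site = _sample_site(rng, pwm)
                if rng.random() < 0.5:
                    site = comp[site][::-1]
                placed = False
                for _attempt in range(100):
                    pos = int(rng.integers(0, config.promoter_len - L + 1))
                    if not occupied[pos : pos + L].any():
                        codes[pos : pos + L] = site
                        occupied[pos : pos + L] = True
                        placed = True
                        break
                if not placed:
                    raise ValueError(
                        f"site insertion overflow in promoter {pid}: "
                        f"{n_sites} sites requested for {config.promoter_len} bases"
                    )
            counts[pid] = n_sites
            seq = _CODE_TO_BASE[codes.astype(np.intp)].tobytes().decode("ascii")
            promoters.append(Promoter(gene, pid, seq))
    truth = SyntheticTruth(
        target_flags=target_flags,
        planted_site_counts=pd.Series(counts, name="planted_sites", dtype=int),
        regulator_gene=regulator_gene,
    )
    return PromoterSet(promoters), truth


def generate_expression(config: SyntheticConfig,
                        truth: SyntheticTruth) -> list[ExpressionComparison]:
    """Two-class Gaussian expression with density-proportional target up-shift.

    The case-class mean of a target gene is raised by
    ``effect_size x (gene planted density / mean target density)``; the
    regulator gene itself is raised by ``effect_size`` so similarity metrics
    have a signed reference.  Noise is redrawn per comparison; the shift is
    deterministic given the truth.
    """
    genes = truth.target_flags.index
    if len(genes) != config.n_genes:
        raise ValueError(
            f"gene universe mismatch: truth has {len(genes)} genes, "
            f"config expects {config.n_genes}"
        )
    shift = np.zeros(len(genes))
    if truth.target_flags.any():
        dens = truth.planted_gene_density(config.promoter_len)
        tmask = truth.target_flags.to_numpy()
        mean_target_density = dens.to_numpy()[tmask].mean()
        if mean_target_density > 0:
            shift[tmask] = (
                config.effect_size
                * dens.to_numpy()[tmask] / mean_target_density
            )
    shift[genes.get_loc(truth.regulator_gene)] = config.effect_size

    rng = np.random.default_rng([config.seed, 2])
    k = config.samples_per_class
    cols = [f"case_{i + 1}" for i in range(k)] + [f"control_{i + 1}" for i in range(k)]
    labels = ["case"] * k + ["control"] * k
    comparisons = []
    for c in range(config.n_comparisons):
        mat = rng.normal(0.0, config.noise_sd, size=(len(genes), 2 * k))
        mat[:, :k] += shift[:, None]
        df = pd.DataFrame(mat, index=genes, columns=cols)
        comparisons.append(ExpressionComparison(df, labels, f"comp{c + 1}"))
    return comparisons


_CATEGORIES = ("pathway", "molecular function", "biological process")


def generate_gene_groups(config: SyntheticConfig,
                         truth: SyntheticTruth) -> dict[str, list[str]]:
    """Gene groups with a controlled number of target-enriched groups.

    The first ``n_enriched_groups`` groups draw
    ``enriched_group_target_fraction`` of members from planted targets and
    the rest uniformly from non-targets; the remaining groups draw uniformly
    from all genes.  Membership is recorded in ``truth.enriched_group_ids``.
    """
    if config.group_size > config.n_genes:
        raise ValueError("group_size exceeds number of genes")
    rng = np.random.default_rng([config.seed, 3])
    genes = np.asarray(truth.target_flags.index)
    targets = genes[truth.target_flags.to_numpy()]
    non_targets = genes[~truth.target_flags.to_numpy()]
    groups: dict[str, list[str]] = {}
    truth.enriched_group_ids = set()
    width = len(str(config.n_groups))
    for i in range(1, config.n_groups + 1):
        name = f"group_{i:0{width}d}"
        if i <= config.n_enriched_groups:
            n_t = round(config.enriched_group_target_fraction * config.group_size)
            n_t = min(n_t, targets.size)
            member_t = rng.choice(targets, size=n_t, replace=False)
            member_n = rng.choice(non_targets, size=config.group_size - n_t,
                                  replace=False)
            members = np.concatenate([member_t, member_n])
            truth.enriched_group_ids.add(name)
        else:
            members = rng.choice(genes, size=config.group_size, replace=False)
        groups[name] = sorted(members.tolist())
    return groups


@dataclass
class SyntheticDataset:
    """All synthetic artifacts for one configuration, in memory."""

    config: SyntheticConfig
    regulator_pwm: PWM
    decoy_pwms: list[PWM]
    promoters: PromoterSet
    truth: SyntheticTruth
    comparisons: list[ExpressionComparison]
    groups: dict[str, list[str]]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run the full generator: motif + decoys, promoters, expression, groups."""
    regulator, decoys = make_regulator_pwm(config.seed, config.n_decoys)
    promoters, truth = generate_promoters(config, regulator)
    comparisons = generate_expression(config, truth)
    groups = generate_gene_groups(config, truth)
    return SyntheticDataset(config, regulator, decoys, promoters, truth,
                            comparisons, groups)
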
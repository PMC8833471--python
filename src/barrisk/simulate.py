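"""Synthetic cohorts with known ground truth.

Two generators, both pure functions of (config, seed):

* ``simulate_genotypes`` draws per-sample risk-allele dosages as
  Binomial(2, f) under Hardy-Weinberg from per-group allele frequencies,
  independently across loci (the emulated panel is a sparse set of lead or
  proxy SNPs, so no linkage disequilibrium is modelled), then masks
  genotypes to missing at a configured rate.  The truth record keeps every
  frequency and exposes the implied allele-count odds ratio between any two
  groups, OR = f_a(1-f_b) / (f_b(1-f_a)).

* ``simulate_counts`` draws gene x sample counts from a negative binomial
  with variance mu + dispersion * mu^2 (gamma-Poisson; dispersion -> 0
  recovers Poisson).  Planted effects multiply a gene's mean by a fold
  change in one condition; a pathway plan groups genes into named sets so
  enrichment is testable against planted membership.

The default configurations emulate the study design the package targets:
a four-group case-control cohort (19 EA/BE, 44 EA-only, 10 BE-only,
730 controls) genotyped at a ~30-SNP Barrett's-risk panel, and a
six-vs-six exposed/unexposed fibroblast count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genotypes import GenotypeMatrix, RiskLocus
from .enrichment import GeneSetCollection

__all__ = [
    "GenotypeSimConfig",
    "GenotypeTruth",
    "simulate_genotypes",
    "default_genotype_config",
    "PlantedEffect",
    "ExpressionSimConfig",
    "ExpressionTruth",
    "simulate_counts",
    "default_expression_config",
]

# default cohort strata: EA/BE, EA-only, BE-only patients plus population controls
DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (
    ("EA/BE", 19),
    ("EA-only", 44),
    ("BE-only", 10),
    ("control", 730),
)


@dataclass
class GenotypeSimConfig:
    """Hardy-Weinberg cohort simulation settings.

    ``frequencies`` maps snp_id -> {group label -> risk-allele frequency}.
    ``loci`` carries the panel metadata (risk allele, published OR) used by
    downstream scoring.
    """

    groups: Sequence[tuple[str, int]]
    loci: Sequence[RiskLocus]
    frequencies: Mapping[str, Mapping[str, float]]
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n in self.groups:
            if n < 1:
                raise ValueError(f"group {label!r} size must be >= 1, got {n}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0,1), got {self.missing_rate}")
        for snp_id, per_group in self.frequencies.items():
            for g, f in per_group.items():
                if not 0 <= f <= 1:
                    raise ValueError(f"{snp_id}/{g}: frequency {f} outside [0,1]")


@dataclass
class GenotypeTruth:
    frequencies: pd.DataFrame  # loci x groups

    def implied_or(self, snp_id: str, group_a: str, group_b: str) -> float:
        """Allele-count odds ratio implied by the true frequencies."""
        fa = self.frequencies.loc[snp_id, group_a]
        fb = self.frequencies.loc[snp_id, group_b]
        return (fa * (1 - fb)) / (fb * (1 - fa))

    def implied_score_shift(
        self, ors: Mapping[str, float], group_a: str, group_b: str
    ) -> float:
        """Expected PGRS difference E[score_a] - E[score_b] under given OR weights."""
        shift = 0.0
        for snp_id, or_value in ors.items():
            fa = self.frequencies.loc[snp_id, group_a]
            fb = self.frequencies.loc[snp_id, group_b]
            shift += np.log(or_value) * 2.0 * (fa - fb)
        return float(shift)


def simulate_genotypes(config: GenotypeSimConfig) -> tuple[GenotypeMatrix, GenotypeTruth]:
    """Draw a cohort of risk-allele dosages under Hardy-Weinberg equilibrium."""
    rng = np.random.default_rng(config.seed)
    sample_ids: list[str] = []
    group_of: dict[str, str] = {}
    for label, n in config.groups:
        safe = label.replace("/", "").replace(" ", "")
        for i in range(n):
            sid = f"{safe}_{i:04d}"
            sample_ids.append(sid)
            group_of[sid] = label

    group_labels = np.array([group_of[s] for s in sample_ids])
    columns = {}
    for locus in config.loci:
        per_group = config.frequencies[locus.snp_id]
        dosage = np.empty(len(sample_ids), dtype=float)
        for label, _ in config.groups:
            mask = group_labels == label
            dosage[mask] = rng.binomial(2, per_group[label], size=mask.sum())
        if config.missing_rate > 0:
            dosage[rng.random(len(sample_ids)) < config.missing_rate] = np.nan
        columns[locus.snp_id] = dosage

    dosage_df = pd.DataFrame(columns, index=sample_ids, dtype=float)
    truth = GenotypeTruth(
        pd.DataFrame(
            {g: [config.frequencies[l.snp_id][g] for l in config.loci] for g, _ in config.groups},
            index=[l.snp_id for l in config.loci],
        )
    )
    return GenotypeMatrix(dosage_df, list(config.loci), group_of), truth


def _case_frequency(f0: float, odds_ratio: float) -> float:
    """Case allele frequency implied by a control frequency and an allelic OR."""
    odds = f0 / (1 - f0) * odds_ratio
    return odds / (1 + odds)


# a fixed ~30-SNP panel shaped like literature Barrett's/EAC risk loci:
# modest ORs, a few protective (<1) alleles, control frequencies spanning
# common variation.  (or, control frequency) per locus.
_PANEL = [
    (1.20, 0.25), (1.30, 0.40), (1.50, 0.15), (0.80, 0.35), (1.24, 0.50),
    (1.40, 0.30), (1.15, 0.45), (0.70, 0.20), (1.60, 0.10), (1.35, 0.55),
    (1.21, 0.60), (1.45, 0.25), (0.75, 0.40), (1.31, 0.35), (1.26, 0.20),
    (1.55, 0.30), (1.10, 0.50), (1.41, 0.45), (0.85, 0.55), (1.22, 0.30),
    (1.51, 0.40), (1.32, 0.20), (1.27, 0.35), (1.36, 0.50), (0.65, 0.25),
    (1.46, 0.15), (1.23, 0.40), (1.33, 0.30), (1.42, 0.60), (1.28, 0.45),
]
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


def default_genotype_config(
    seed: int = 0,
    groups: Sequence[tuple[str, int]] = DEFAULT_GROUPS,
    case_group: str = "EA/BE",
    missing_rate: float = 0.02,
) -> GenotypeSimConfig:
    """The default four-group cohort at a fixed 30-SNP risk panel.

    Every group shares the control allele frequency except ``case_group``,
    whose frequency at each locus is elevated (or, for protective alleles,
    depressed) so the true allelic OR versus the other groups equals the
    locus's published OR — the scenario where the literature weights are
    exactly right for the case phenotype.
    """
    loci = []
    frequencies: dict[str, dict[str, float]] = {}
    for i, (or_value, f0) in enumerate(_PANEL):
        risk, other = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        snp_id = f"rs{900000 + i}"
        loci.append(
            RiskLocus(
                snp_id=snp_id,
                risk_allele=risk,
                other_allele=other,
                published_or=or_value,
                phenotype_tag="BE",
                source_tag="synthetic-panel",
            )
        )
        f_case = _case_frequency(f0, or_value)
        frequencies[snp_id] = {
            label: (f_case if label == case_group else f0) for label, _ in groups
        }
    return GenotypeSimConfig(
        groups=tuple(groups),
        loci=loci,
        frequencies=frequencies,
        missing_rate=missing_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# expression simulation


@dataclass
class PlantedEffect:
    """A fold change applied to a gene subset in one condition."""

    genes: tuple[str, ...]
    fold_change: float
    direction: str  # "up" | "down"
    condition: str  # condition whose mean is multiplied/divided

    def __post_init__(self) -> None:
        if self.fold_change < 1:
            raise ValueError(f"fold change must be >= 1, got {self.fold_change}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")


@dataclass
class ExpressionSimConfig:
    """Negative-binomial count simulation settings.

    Variance parametrization: Var = mu + dispersion * mu^2 (dispersion 0
    gives Poisson).  ``baseline_mean`` is the median per-gene mean count;
    per-gene means are drawn log-normally around it (sigma
    ``mean_log_sigma``) so the expression floor has a realistic spread to
    act on.  ``pathway_plan`` maps set name -> gene ids, letting enrichment
    be checked against planted membership.
    """

    n_genes: int
    conditions: Sequence[tuple[str, int]]
    gene_lengths: Sequence[int] | int = 1000
    baseline_mean: float = 100.0
    mean_log_sigma: float = 1.0
    dispersion: float = 0.1
    effects: Sequence[PlantedEffect] = ()
    pathway_plan: Mapping[str, Sequence[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        for label, n in self.conditions:
            if n < 1:
                raise ValueError(f"condition {label!r} size must be >= 1")


@dataclass
class ExpressionTruth:
    de_genes: set[str]  # genes with a planted fold change
    means: pd.DataFrame  # genes x conditions true means
    pathways: GeneSetCollection | None


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mu))


def simulate_counts(config: ExpressionSimConfig) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Draw a gene x sample count matrix with planted condition effects."""
    rng = np.random.default_rng(config.seed)
    genes = [f"gene{i:05d}" for i in range(config.n_genes)]
    if isinstance(config.gene_lengths, int):
        lengths = pd.Series(float(config.gene_lengths), index=genes)
    else:
        if len(config.gene_lengths) != config.n_genes:
            raise ValueError("gene_lengths must match n_genes")
        lengths = pd.Series([float(x) for x in config.gene_lengths], index=genes)

    base = config.baseline_mean * np.exp(
        rng.normal(0.0, config.mean_log_sigma, size=config.n_genes)
    )
    cond_labels = [label for label, _ in config.conditions]
    means = pd.DataFrame(
        {label: base.copy() for label in cond_labels}, index=genes
    )
    planted: set[str] = set()
    gene_pos = {g: i for i, g in enumerate(genes)}
    for effect in config.effects:
        if effect.condition not in cond_labels:
            raise ValueError(f"effect condition {effect.condition!r} not simulated")
        factor = effect.fold_change if effect.direction == "up" else 1.0 / effect.fold_change
        if factor != 1.0:
            planted.update(effect.genes)
        idx = [gene_pos[g] for g in effect.genes]
        means.iloc[idx, means.columns.get_loc(effect.condition)] *= factor

    columns: dict[str, np.ndarray] = {}
    condition_of: dict[str, str] = {}
    for label, n in config.conditions:
        mu = means[label].to_numpy()
        safe = label.replace(" ", "")
        for i in range(n):
            sid = f"{safe}_{i:03d}"
            columns[sid] = _nb_draw(rng, mu, config.dispersion)
            condition_of[sid] = label

    counts = pd.DataFrame(columns, index=genes, dtype=int)
    pathways = None
    if config.pathway_plan:
        pathways = GeneSetCollection(
            {name: set(members) for name, members in config.pathway_plan.items()},
            universe=set(genes),
        )
    truth = ExpressionTruth(planted, means, pathways)
    return ExpressionMatrix(counts, lengths, condition_of), truth


def default_expression_config(
    seed: int = 0,
    n_genes: int = 4000,
    conditions: Sequence[tuple[str, int]] = (("exposed", 6), ("unexposed", 6)),
    n_de: int = 200,
    fold_change: float = 3.0,
    n_pathways: int = 25,
    pathway_size: int = 40,
    de_fraction_enriched: float = 0.5,
) -> ExpressionSimConfig:
    """An exposed-vs-unexposed fibroblast-style design with planted pathways.

    ``n_de`` genes get a fold change in the first condition (half up, half
    down).  ``n_pathways`` gene sets of ``pathway_size`` are planted: the
    first few draw ``de_fraction_enriched`` of their members from the DE
    genes (truly enriched), the rest are background sets.
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    de_genes = list(rng.choice(genes, size=n_de, replace=False))
    half = n_de // 2
    target = conditions[0][0]
    effects = [
        PlantedEffect(tuple(de_genes[:half]), fold_change, "up", target),
        PlantedEffect(tuple(de_genes[half:]), fold_change, "down", target),
    ]

    non_de = [g for g in genes if g not in set(de_genes)]
    n_enriched = max(1, n_pathways // 5)
    plan: dict[str, list[str]] = {}
    de_pool = list(de_genes)
    for i in range(n_pathways):
        if i < n_enriched and de_pool:
            n_from_de = int(pathway_size * de_fraction_enriched)
            take = list(rng.choice(de_pool, size=min(n_from_de, len(de_pool)), replace=False))
            rest = list(rng.choice(non_de, size=pathway_size - len(take), replace=False))
            plan[f"planted_pathway_{i:02d}"] = take + rest
        else:
            plan[f"background_pathway_{i:02d}"] = list(
                rng.choice(non_de, size=pathway_size, replace=False)
            )
    return ExpressionSimConfig(
        n_genes=n_genes,
        conditions=tuple(conditions),
        gene_lengths=[int(l) for l in rng.integers(500, 5000, size=n_genes)],
        baseline_mean=100.0,
        mean_log_sigma=1.0,
        dispersion=0.1,
        effects=effects,
        pathway_plan=plan,
        seed=seed,
    )
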
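"""Additive polygenic risk scores and case-control allele association.

The score follows the additive log-odds model

    PGRS_s = sum_j ln(OR_j) * dosage_{s,j}

where ``dosage`` counts risk alleles (0-2) and ``OR_j`` is the per-locus
odds ratio, either published (literature weights) or re-estimated from the
cohort's own allele counts (in-sample weights).  An OR below 1 encodes a
protective risk-labelled allele and enters the sum as a negative weight;
loci are never re-polarized.

Score distributions are compared across groups nonparametrically: an
omnibus Kruskal-Wallis test plus all pairwise two-sided Mann-Whitney tests,
exact when both groups are small and tie-free, otherwise the normal
approximation with tie correction.  Per-SNP association uses allele-count
2x2 tables (two alleles per diploid sample): OR = ad/bc with the
Haldane-Anscombe +0.5 fallback when a cell is empty, and Fisher's exact
p on the uncorrected table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, RiskLocus

__all__ = [
    "MissingPolicy",
    "compute_pgrs",
    "estimate_insample_ors",
    "compare_groups",
    "GroupComparisonResult",
    "PolygenicScoreModel",
    "PolygenicScoreResults",
    "write_score_table",
]

EXACT_MAX_N = 10  # exact Mann-Whitney enumeration when both groups <= this and tie-free


class MissingPolicy:
    IMPUTE_FREQUENCY = "impute_frequency"
    OMIT_LOCUS = "omit_locus"
    OMIT_SAMPLE = "omit_sample"


def compute_pgrs(
    genotypes: GenotypeMatrix,
    weights: Mapping[str, float],
    or_source: str = "literature",
    missing_policy: str = MissingPolicy.IMPUTE_FREQUENCY,
) -> pd.DataFrame:
    """Per-sample additive score: sum over loci of ln(OR) x risk-allele dosage.

    Parameters
    ----------
    weights
        snp_id -> odds ratio (not log OR); every key must be a panel locus.
    missing_policy
        How a missing dosage enters the sum: ``impute_frequency`` (default)
        replaces it with 2x the cohort risk-allele frequency at that locus,
        ``omit_locus`` contributes 0, ``omit_sample`` drops the sample.

    Returns a DataFrame indexed by sample with columns
    group, score, or_source, n_loci_used, n_imputed.
    """
    snp_ids = [s for s in genotypes.locus_ids if s in weights]
    unknown = set(weights) - set(genotypes.locus_ids)
    if unknown:
        raise ValueError(f"weights refer to loci absent from the matrix: {sorted(unknown)}")
    if not snp_ids:
        raise ValueError("empty locus set: no weighted locus survives harmonization")
    ors = np.array([weights[s] for s in snp_ids], dtype=float)
    if np.any(~np.isfinite(ors)) or np.any(ors <= 0):
        bad = [s for s, o in zip(snp_ids, ors) if not (np.isfinite(o) and o > 0)]
        raise ValueError(f"odds ratios must be positive and finite: {bad}")
    log_or = np.log(ors)

    dosage = genotypes.dosage[snp_ids].to_numpy(dtype=float)
    missing = np.isnan(dosage)
    n_imputed = missing.sum(axis=1)

    if missing_policy == MissingPolicy.IMPUTE_FREQUENCY:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing column
            freq = np.nanmean(dosage, axis=0) / 2.0
        freq = np.where(np.isnan(freq), 0.0, freq)
        filled = np.where(missing, 2.0 * freq[None, :], dosage)
    elif missing_policy == MissingPolicy.OMIT_LOCUS:
        filled = np.where(missing, 0.0, dosage)
    elif missing_policy == MissingPolicy.OMIT_SAMPLE:
        filled = dosage
    else:
        raise ValueError(f"unknown missing policy {missing_policy!r}")

    scores = filled @ log_or
    table = pd.DataFrame(
        {
            "group": genotypes.group_of,
            "score": scores,
            "or_source": or_source,
            "n_loci_used": len(snp_ids),
            "n_imputed": n_imputed,
        },
        index=genotypes.dosage.index,
    )
    if missing_policy == MissingPolicy.OMIT_SAMPLE:
        table = table[~np.isnan(table["score"])]
    if not np.isfinite(table["score"]).all():
        raise ValueError("non-finite score produced")  # pragma: no cover
    return table


def _allele_counts(dosage: np.ndarray) -> tuple[int, int]:
    """(risk, other) allele counts over non-missing diploid dosages."""
    d = dosage[~np.isnan(dosage)]
    risk = int(d.sum())
    return risk, int(2 * len(d) - risk)


def estimate_insample_ors(
    genotypes: GenotypeMatrix,
    case_group: str,
    control_group: str,
) -> pd.DataFrame:
    """Per-SNP allele-count odds ratios between two cohort groups.

    For each locus a 2x2 allele table is formed (a=case risk, b=case other,
    c=control risk, d=control other; 2 alleles per non-missing sample) and
    OR = (a*d)/(b*c).  Any zero cell triggers the Haldane-Anscombe +0.5
    correction on all four cells for the point estimate (flagged in the
    ``corrected`` column); Fisher's exact two-sided p is always computed on
    the raw counts.  A group with zero non-missing genotypes at a SNP gives
    an undefined (NaN) OR with a warning rather than an exception.
    """
    groups = genotypes.group_of
    for g in (case_group, control_group):
        if g not in set(groups):
            raise ValueError(f"group {g!r} absent from the genotype matrix")
    case_idx = groups[groups == case_group].index
    ctrl_idx = groups[groups == control_group].index

    rows = []
    for snp_id in genotypes.locus_ids:
        a, b = _allele_counts(genotypes.dosage.loc[case_idx, snp_id].to_numpy())
        c, d = _allele_counts(genotypes.dosage.loc[ctrl_idx, snp_id].to_numpy())
        if a + b == 0 or c + d == 0:
            warnings.warn(f"{snp_id}: a group has no non-missing genotypes; OR undefined")
            rows.append((snp_id, np.nan, np.nan, a, b, c, d, False))
            continue
        corrected = 0 in (a, b, c, d)
        if corrected:
            or_est = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            or_est = (a * d) / (b * c)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((snp_id, or_est, p, a, b, c, d, corrected))
    return pd.DataFrame(
        rows,
        columns=["snp_id", "odds_ratio", "p_value", "a", "b", "c", "d", "corrected"],
    ).set_index("snp_id")


@dataclass
class GroupComparisonResult:
    """Omnibus Kruskal-Wallis result plus all pairwise Mann-Whitney tests."""

    omnibus_statistic: float
    omnibus_p: float
    groups: list[str]
    pairwise: pd.DataFrame  # group_a, group_b, u_statistic, p_value, method

    def to_dict(self) -> dict:
        return {
            "omnibus": {
                "test": "kruskal-wallis",
                "statistic": self.omnibus_statistic,
                "p_value": self.omnibus_p,
                "groups": self.groups,
            },
            "pairwise": self.pairwise.to_dict(orient="records"),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "normal-approximation-with-tie-correction"


def compare_groups(
    scores: pd.DataFrame,
    groups: Sequence[str],
    bonferroni: bool = False,
) -> GroupComparisonResult:
    """Kruskal-Wallis omnibus plus pairwise two-sided Mann-Whitney tests.

    ``scores`` is a compute_pgrs-style table with ``group`` and ``score``
    columns; samples outside the requested groups are excluded from the
    comparison.  Pairwise p values are raw by default; ``bonferroni=True``
    multiplies them by the number of pairs (capped at 1).
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    present = set(scores["group"])
    for g in groups:
        if g not in present:
            raise ValueError(f"group {g!r} absent from the score table")
    samples = {g: scores.loc[scores["group"] == g, "score"].to_numpy(dtype=float) for g in groups}
    for g, v in samples.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} has no scores")

    h, p = stats.kruskal(*[samples[g] for g in groups])

    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ga, gb = groups[i], groups[j]
            u, pv, method = _mannwhitney(samples[ga], samples[gb])
            if bonferroni:
                pv = min(1.0, pv * n_pairs)
            rows.append((ga, gb, u, pv, method))
    pairwise = pd.DataFrame(
        rows, columns=["group_a", "group_b", "u_statistic", "p_value", "method"]
    )
    return GroupComparisonResult(float(h), float(p), groups, pairwise)


# ---------------------------------------------------------------------------
# model / results surface


class PolygenicScoreModel:
    """Additive polygenic risk score over a harmonized genotype cohort.

    Parameters
    ----------
    genotypes
        Harmonized risk-allele dosages with group labels.
    or_source
        ``"literature"`` scores with the panel's published ORs;
        ``"in_sample"`` re-estimates each locus's OR from the cohort's own
        allele counts between ``case_group`` and ``control_group`` first.
    case_group, control_group
        Required for in-sample weighting; which cohort strata define the
        allele 2x2 tables is an explicit user choice.
    missing_policy
        Passed through to :func:`compute_pgrs`.

    Examples
    --------
    >>> model = PolygenicScoreModel(cohort, or_source="literature")
    >>> res = model.fit(compare=["EA/BE", "EA-only", "BE-only"])
    >>> res.median_by_group()
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        or_source: str = "literature",
        case_group: str | None = None,
        control_group: str | None = None,
        missing_policy: str = MissingPolicy.IMPUTE_FREQUENCY,
    ) -> None:
        if or_source not in ("literature", "in_sample"):
            raise ValueError("or_source must be 'literature' or 'in_sample'")
        if or_source == "in_sample" and not (case_group and control_group):
            raise ValueError("in-sample weighting needs case_group and control_group")
        self.genotypes = genotypes
        self.or_source = or_source
        self.case_group = case_group
        self.control_group = control_group
        self.missing_policy = missing_policy

    def fit(self, compare: Sequence[str] | None = None) -> "PolygenicScoreResults":
        """Score every sample; optionally compare score distributions.

        ``compare`` lists the group labels whose score distributions are
        tested (omnibus + pairwise); ``None`` skips the comparison.
        """
        if self.or_source == "literature":
            weights = {l.snp_id: l.published_or for l in self.genotypes.loci}
            association = None
        else:
            association = estimate_insample_ors(
                self.genotypes, self.case_group, self.control_group
            )
            defined = association["odds_ratio"].dropna()
            weights = defined.to_dict()
        scores = compute_pgrs(self.genotypes, weights, self.or_source, self.missing_policy)
        comparison = compare_groups(scores, compare) if compare is not None else None
        return PolygenicScoreResults(self, scores, weights, association, comparison)


class PolygenicScoreResults:
    """Fitted per-sample scores, per-SNP weights and group comparisons."""

    def __init__(
        self,
        model: PolygenicScoreModel,
        scores: pd.DataFrame,
        weights: Mapping[str, float],
        association: pd.DataFrame | None,
        comparison: GroupComparisonResult | None,
    ) -> None:
        self.model = model
        self.scores = scores
        self.weights = dict(weights)
        self.association = association
        self.comparison = comparison

    def median_by_group(self) -> pd.Series:
        return self.scores.groupby("group")["score"].median()

    def summary(self) -> str:
        lines = [
            "Polygenic risk score results",
            f"  OR source:      {self.model.or_source}",
            f"  loci used:      {int(self.scores['n_loci_used'].iloc[0])}",
            f"  samples scored: {len(self.scores)}",
            "",
            "  median score by group:",
        ]
        med = self.median_by_group()
        rng = self.scores.groupby("group")["score"].agg(["min", "max"])
        for g in med.index:
            lines.append(
                f"    {g:<12} {med[g]:8.3f}  (range {rng.loc[g, 'min']:.2f} to {rng.loc[g, 'max']:.2f})"
            )
        if self.comparison is not None:
            c = self.comparison
            lines += [
                "",
                f"  Kruskal-Wallis H = {c.omnibus_statistic:.3f}, p = {c.omnibus_p:.4g}",
                "  pairwise Mann-Whitney (two-sided):",
            ]
            for _, r in c.pairwise.iterrows():
                lines.append(
                    f"    {r['group_a']} vs {r['group_b']}: U = {r['u_statistic']:.1f}, "
                    f"p = {r['p_value']:.4g} [{r['method']}]"
                )
        return "\n".join(lines)

    def plot(self, ax=None, groups: Sequence[str] | None = None):
        """Jittered strip plot of per-sample scores by group with medians."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.5 * len(set(self.scores["group"])), 4))
        groups = list(groups) if groups is not None else sorted(set(self.scores["group"]))
        rng = np.random.default_rng(0)
        for i, g in enumerate(groups):
            values = self.scores.loc[self.scores["group"] == g, "score"]
            x = i + rng.uniform(-0.15, 0.15, len(values))
            ax.plot(x, values, "o", ms=3, alpha=0.4)
            ax.hlines(values.median(), i - 0.25, i + 0.25, color="black", lw=2)
        ax.set_xticks(range(len(groups)), groups)
        ax.set_ylabel("PGRS (ln-odds units)")
        ax.set_title(f"Polygenic risk score ({self.model.or_source} ORs)")
        return ax


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    out = scores.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.10g")
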
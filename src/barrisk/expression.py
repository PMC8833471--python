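"""Count normalization, threshold differential-expression filtering and QC.

The differential-expression call here is deliberately a *filter*, not a
dispersion-modelling framework: a gene passes when all three of

    max(group mean) > 2      (normalized units, RPKM by default)
    fold change    >= 1.5    (larger group mean over smaller, linear scale)
    BH FDR q       <  0.05

hold.  The per-gene p comes from Welch's unequal-variance t on
log2(normalized + 1) by default (a rank-sum alternative is available);
the pass rule is threshold-driven, so the filter's behaviour is dominated
by the three cuts rather than by the choice of test.

An expression floor (mean >= 2 RPKM across all samples) defines the set of
"expressed" genes before testing, and a gene-set subtraction removes genes
that respond in a baseline contrast (e.g. unexposed cells) from an exposure
contrast's hit list.  PCA-based QC flags outlying samples but never drops
them silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "read_count_table",
    "write_count_table",
    "read_condition_map",
    "normalize",
    "expression_floor",
    "differential_expression",
    "DifferentialExpressionModel",
    "DifferentialExpressionResults",
    "SubtractionReport",
    "subtract_baseline",
    "pca_qc",
    "QCReport",
]


class ExpressionMatrix:
    """Gene x sample raw counts with RPKM/TPM layers and condition labels.

    ``raw_counts`` is genes x samples (non-negative integers),
    ``gene_lengths`` is in bases.  Normalized layers are attached by
    :func:`normalize`.
    """

    def __init__(
        self,
        raw_counts: pd.DataFrame,
        gene_lengths: pd.Series,
        condition_of: Mapping[str, str],
    ) -> None:
        if not raw_counts.index.equals(gene_lengths.index):
            gene_lengths = gene_lengths.reindex(raw_counts.index)
        if gene_lengths.isna().any() or (gene_lengths <= 0).any():
            bad = gene_lengths.index[gene_lengths.isna() | (gene_lengths <= 0)]
            raise ValueError(f"gene lengths must be positive for all genes; bad: {list(bad)[:5]}")
        if (raw_counts.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")
        missing = [s for s in raw_counts.columns if s not in condition_of]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")
        self.raw_counts = raw_counts
        self.gene_lengths = gene_lengths.astype(float)
        self.condition_of = pd.Series(
            {s: condition_of[s] for s in raw_counts.columns}, name="condition"
        )
        self.rpkm: pd.DataFrame | None = None
        self.tpm: pd.DataFrame | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.raw_counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.raw_counts.columns)

    def layer(self, name: str) -> pd.DataFrame:
        value = {"rpkm": self.rpkm, "tpm": self.tpm, "counts": self.raw_counts}[name]
        if value is None:
            raise ValueError(f"layer {name!r} not computed; call normalize() first")
        return value


def normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Attach RPKM and TPM layers.

    RPKM_gs = count_gs * 1e9 / (length_g * total_counts_s);
    TPM_gs = rate_gs * 1e6 / sum_g rate_gs with rate_gs = count_gs / length_g,
    so TPM sums to one million within every sample.
    """
    counts = matrix.raw_counts.to_numpy(dtype=float)
    lengths = matrix.gene_lengths.to_numpy(dtype=float)[:, None]
    totals = counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"sample(s) with zero total counts: {[matrix.samples[i] for i in zero]}")
    rpkm = counts * 1e9 / (lengths * totals[None, :])
    rate = counts / lengths
    tpm = rate * 1e6 / rate.sum(axis=0)[None, :]
    matrix.rpkm = pd.DataFrame(rpkm, index=matrix.raw_counts.index, columns=matrix.raw_counts.columns)
    matrix.tpm = pd.DataFrame(tpm, index=matrix.raw_counts.index, columns=matrix.raw_counts.columns)
    return matrix


def expression_floor(
    matrix: ExpressionMatrix, threshold: float = 2.0, layer: str = "rpkm"
) -> list[str]:
    """Genes whose mean normalized expression across all samples is >= threshold.

    The boundary is inclusive: a gene sitting exactly at the threshold is
    considered expressed.
    """
    values = matrix.layer(layer)
    mean = values.mean(axis=1)
    return list(mean.index[mean >= threshold])


# ---------------------------------------------------------------------------
# differential expression


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    genes: Sequence[str] | None = None,
    layer: str = "rpkm",
    max_mean_threshold: float = 2.0,
    fc_threshold: float = 1.5,
    q_threshold: float = 0.05,
    test: str = "welch",
) -> pd.DataFrame:
    """Three-criterion differential-expression filter between two conditions.

    Per gene: group means on the normalized scale; direction-symmetric fold
    change max(mean)/min(mean) (infinite when the smaller mean is zero, which
    satisfies the fold-change cut); two-sided p on log2(normalized + 1)
    (Welch's t by default, ``test="ranksum"`` for Mann-Whitney);
    Benjamini-Hochberg q across the tested genes.  A gene passes iff
    max group mean > ``max_mean_threshold``, fold change >= ``fc_threshold``
    and q < ``q_threshold``.
    """
    cond = matrix.condition_of
    idx_a = cond.index[cond == group_a]
    idx_b = cond.index[cond == group_b]
    for g, idx in ((group_a, idx_a), (group_b, idx_b)):
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has {len(idx)} samples; need at least 2")
    values = matrix.layer(layer)
    if genes is not None:
        values = values.loc[list(genes)]
    a = values[idx_a].to_numpy(dtype=float)
    b = values[idx_b].to_numpy(dtype=float)

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    hi = np.maximum(mean_a, mean_b)
    lo = np.minimum(mean_a, mean_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, 1.0))
    direction = np.where(mean_a >= mean_b, "up", "down")

    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    if test == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance-everywhere genes
    elif test == "ranksum":
        p = np.array(
            [
                stats.mannwhitneyu(la[i], lb[i], alternative="two-sided").pvalue
                if not np.allclose(la[i], lb[i])
                else 1.0
                for i in range(la.shape[0])
            ]
        )
    else:
        raise ValueError(f"unknown test {test!r}")

    _, q, _, _ = multipletests(p, method="fdr_bh")
    passed = (hi > max_mean_threshold) & (fc >= fc_threshold) & (q < q_threshold)

    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "direction": direction,
            "p_value": p,
            "q_value": q,
            "pass": passed,
        },
        index=values.index,
    )


class DifferentialExpressionModel:
    """Two-condition expression contrast under the threshold filter.

    Wraps :func:`normalize`, :func:`expression_floor` and
    :func:`differential_expression` into a fit-once surface.

    Parameters
    ----------
    matrix
        Raw counts with condition labels (normalized lazily if needed).
    group_a, group_b
        Condition labels to contrast; ``direction`` in the results is
        relative to ``group_a``.
    floor_threshold
        Mean-RPKM floor defining the expressed-gene universe (inclusive).
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        group_a: str,
        group_b: str,
        floor_threshold: float = 2.0,
        max_mean_threshold: float = 2.0,
        fc_threshold: float = 1.5,
        q_threshold: float = 0.05,
        layer: str = "rpkm",
        test: str = "welch",
    ) -> None:
        self.matrix = matrix
        self.group_a = group_a
        self.group_b = group_b
        self.floor_threshold = floor_threshold
        self.max_mean_threshold = max_mean_threshold
        self.fc_threshold = fc_threshold
        self.q_threshold = q_threshold
        self.layer = layer
        self.test = test

    def fit(self) -> "DifferentialExpressionResults":
        if self.matrix.rpkm is None:
            normalize(self.matrix)
        expressed = expression_floor(self.matrix, self.floor_threshold, self.layer)
        table = differential_expression(
            self.matrix,
            self.group_a,
            self.group_b,
            genes=expressed,
            layer=self.layer,
            max_mean_threshold=self.max_mean_threshold,
            fc_threshold=self.fc_threshold,
            q_threshold=self.q_threshold,
            test=self.test,
        )
        return DifferentialExpressionResults(self, expressed, table)


class DifferentialExpressionResults:
    """Expressed-gene universe plus the per-gene filter table."""

    def __init__(
        self,
        model: DifferentialExpressionModel,
        expressed_genes: list[str],
        table: pd.DataFrame,
    ) -> None:
        self.model = model
        self.expressed_genes = expressed_genes
        self.table = table

    @property
    def de_genes(self) -> set[str]:
        return set(self.table.index[self.table["pass"]])

    def summary(self) -> str:
        m = self.model
        n_up = int(((self.table["pass"]) & (self.table["direction"] == "up")).sum())
        n_down = int(((self.table["pass"]) & (self.table["direction"] == "down")).sum())
        return "\n".join(
            [
                "Differential expression filter results",
                f"  contrast:        {m.group_a} vs {m.group_b}",
                f"  expressed genes: {len(self.expressed_genes)} "
                f"(mean {m.layer.upper()} >= {m.floor_threshold:g})",
                f"  pass rule:       max group mean > {m.max_mean_threshold:g}, "
                f"FC >= {m.fc_threshold:g}, BH q < {m.q_threshold:g}",
                f"  passing genes:   {len(self.de_genes)} ({n_up} up, {n_down} down in {m.group_a})",
            ]
        )

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# baseline subtraction


@dataclass
class SubtractionReport:
    n_exposed: int
    n_baseline: int
    n_intersection: int
    n_remaining: int
    remaining: set[str]

    def __str__(self) -> str:
        return (
            f"exposed {self.n_exposed} \\ baseline {self.n_baseline}: "
            f"{self.n_intersection} shared, {self.n_remaining} remaining"
        )


def subtract_baseline(de_exposed: set[str], de_baseline: set[str]) -> SubtractionReport:
    """Remove baseline-responsive genes from an exposure hit list.

    Returns the set difference exposed \\ baseline together with the size
    bookkeeping (|exposed|, |baseline|, |intersection|, |remaining|).
    """
    de_exposed = set(de_exposed)
    de_baseline = set(de_baseline)
    remaining = de_exposed - de_baseline
    return SubtractionReport(
        n_exposed=len(de_exposed),
        n_baseline=len(de_baseline),
        n_intersection=len(de_exposed & de_baseline),
        n_remaining=len(remaining),
        remaining=remaining,
    )


# ---------------------------------------------------------------------------
# PCA QC


@dataclass
class QCReport:
    coordinates: pd.DataFrame  # samples x PCs
    variance_explained: np.ndarray
    distances: pd.Series  # distance to own-group centroid in PC space
    outlier: pd.Series  # boolean per sample

    def flagged(self) -> list[str]:
        return list(self.outlier.index[self.outlier])


def pca_qc(
    matrix: ExpressionMatrix,
    k: int = 2,
    genes: Sequence[str] | None = None,
    layer: str = "rpkm",
    mad_multiplier: float = 3.0,
) -> QCReport:
    """PCA of log2(normalized + 1) expression with group-centroid outlier flags.

    Samples are observations, genes features (gene-centered by the PCA).  A
    sample is flagged when its Euclidean distance from its condition-group
    centroid in the first ``k`` PCs exceeds median + ``mad_multiplier`` x MAD
    of the within-group distances.  Flags are reported, never applied:
    excluding a sample is an explicit user decision.
    """
    from sklearn.decomposition import PCA

    if len(matrix.samples) < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    if k >= len(matrix.samples):
        raise ValueError(f"k={k} must be smaller than the number of samples ({len(matrix.samples)})")
    values = matrix.layer(layer)
    if genes is not None:
        values = values.loc[list(genes)]
    x = np.log2(values.to_numpy(dtype=float).T + 1.0)  # samples x genes
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    coordinates = pd.DataFrame(
        coords, index=matrix.samples, columns=[f"PC{i+1}" for i in range(k)]
    )

    cond = matrix.condition_of
    distances = pd.Series(0.0, index=coordinates.index)
    for group in cond.unique():
        idx = cond.index[cond == group]
        centroid = coordinates.loc[idx].mean(axis=0)
        distances[idx] = np.linalg.norm(coordinates.loc[idx] - centroid, axis=1)
    med = distances.groupby(cond).median()
    mad = distances.groupby(cond).agg(lambda v: np.median(np.abs(v - np.median(v))))
    cutoff = (med + mad_multiplier * mad).reindex(cond.to_numpy())
    cutoff.index = cond.index
    outlier = distances > cutoff
    return QCReport(coordinates, pca.explained_variance_ratio_, distances, outlier)


# ---------------------------------------------------------------------------
# tabular I/O


def read_count_table(path: str | Path, condition_of: Mapping[str, str]) -> ExpressionMatrix:
    """Tab-delimited genes x samples count table with a gene_length column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if "gene_length" not in df.columns:
        raise ValueError(f"{path}: count table lacks a gene_length column")
    lengths = df["gene_length"].astype(float)
    counts = df.drop(columns=["gene_length"])
    return ExpressionMatrix(counts, lengths, condition_of)


def write_count_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.raw_counts.copy()
    out.insert(0, "gene_length", matrix.gene_lengths.astype(int))
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_condition_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "condition"], dtype=str)
    return dict(zip(df["sample_id"], df["condition"]))
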
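"""Gene-set over-representation, significance convention, and cross-experiment overlap.

Over-representation of a gene set among a differential list is scored with
the upper-tail hypergeometric probability (at least the observed overlap,
drawing |DE list| genes from the universe with the set as successes).  A
simple directional summary accompanies it:

    z = (n_up - n_down) / sqrt(n_up + n_down)

over the set's differential members, undefined when the overlap is empty.
This z is a transparent stand-in for proprietary pathway-activation scores:
it preserves the decision structure (a p cut plus a |z| cut) without any
curated causal-edge knowledge base, and its numeric values are not expected
to match any commercial tool's output.

The significance convention is p < 0.05 AND |z| >= 2; sets whose z is
undefined can be judged in p-only mode (annotated), mirroring published
tables that print N/A for incomputable activation scores.  Overlap tables
collect per-experiment (-log10 p, z) cells for every pathway enriched
anywhere, and report the pathways enriched in a designated pair of
experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "overrepresentation",
    "apply_significance",
    "overlap_experiments",
    "OverlapTable",
    "shared_gene_report",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the gene universe they are scored against."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        empty = [name for name, members in self.sets.items() if not members]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")

    def restricted(self, name: str) -> set[str]:
        """Set members intersected with the universe."""
        return self.sets[name] & self.universe


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read GMT (set name, description, tab-separated member genes)."""
    sets: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: GMT rows need name, description, >=1 gene")
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return GeneSetCollection(sets, universe or set().union(*sets.values()))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, ""] + sorted(members)) + "\n")


def overrepresentation(
    de_genes: set[str],
    collection: GeneSetCollection,
    directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set among a DE list.

    p = P(X >= overlap) for X ~ Hypergeom(universe, set-in-universe, |DE|).
    ``directions`` optionally maps DE genes to "up"/"down"; when given, each
    set gets direction_z = (n_up - n_down)/sqrt(n_up + n_down) over its DE
    members (NaN when the overlap is empty).  DE genes outside the universe
    are dropped with a warning.
    """
    universe = collection.universe
    if not universe:
        raise ValueError("empty gene universe")
    de_genes = set(de_genes)
    if not de_genes:
        raise ValueError("empty DE gene list")
    outside = de_genes - universe
    if outside:
        warnings.warn(f"{len(outside)} DE genes outside the universe dropped")
        de_genes = de_genes & universe
        if not de_genes:
            raise ValueError("no DE genes remain inside the universe")

    m = len(universe)
    n_draw = len(de_genes)
    rows = []
    for name in collection.sets:
        members = collection.restricted(name)
        k_set = len(members)
        overlap = de_genes & members
        k = len(overlap)
        # upper tail: P(X >= k) = sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, m, k_set, n_draw))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        if directions is not None and k > 0:
            n_up = sum(1 for g in overlap if directions.get(g) == "up")
            n_down = sum(1 for g in overlap if directions.get(g) == "down")
            z = (n_up - n_down) / np.sqrt(n_up + n_down) if (n_up + n_down) else np.nan
        else:
            z = np.nan
        rows.append((name, k, k_set, p, -np.log10(p), z))
    table = pd.DataFrame(
        rows,
        columns=["pathway", "overlap", "set_size", "p_value", "neg_log10_p", "direction_z"],
    ).set_index("pathway")
    return apply_significance(table)


def apply_significance(
    table: pd.DataFrame,
    p_cut: float = 0.05,
    z_cut: float = 2.0,
    p_only: bool = False,
) -> pd.DataFrame:
    """Set the significance flag: p < p_cut AND |direction_z| >= z_cut.

    Sets whose direction_z is undefined (NaN) are always judged on p alone
    and annotated ``z_undefined``; ``p_only=True`` extends the p-only rule
    to every set.
    """
    table = table.copy()
    p_ok = table["p_value"] < p_cut
    z = table["direction_z"]
    z_undefined = z.isna()
    if p_only:
        significant = p_ok
    else:
        significant = p_ok & (z_undefined | (z.abs() >= z_cut))
    table["significant"] = significant
    table["z_undefined"] = z_undefined
    return table


@dataclass
class OverlapTable:
    """Wide pathway x experiment table of (-log10 p, z) with the pair intersection."""

    wide: pd.DataFrame  # MultiIndex columns (experiment, metric); NaN = absent
    pair: tuple[str, str]
    overlap_pathways: list[str]

    @property
    def n_overlap(self) -> int:
        return len(self.overlap_pathways)

    def write(self, path: str | Path) -> None:
        out = self.wide.copy()
        out.columns = [f"{exp}:{metric}" for exp, metric in out.columns]
        out.index.name = "pathway"
        out.to_csv(path, sep="\t", float_format="%.4g", na_rep="NA")


def overlap_experiments(
    tables: Mapping[str, pd.DataFrame],
    pair: tuple[str, str],
) -> OverlapTable:
    """Cross-experiment pathway overlap.

    ``tables`` maps experiment name -> enrichment table (with significance
    flags applied).  The wide output lists every pathway significant in at
    least one experiment, with per-experiment (-log10 p, z) cells (NaN where
    a pathway was not scored in that experiment).  The overlap list holds
    the pathways significant in *both* members of ``pair``; it is symmetric
    in the pair and idempotent on identical inputs.
    """
    if len(tables) < 2:
        raise ValueError("overlap needs at least two experiments")
    for name in pair:
        if name not in tables:
            raise ValueError(f"unknown experiment {name!r}; have {sorted(tables)}")

    enriched = {name: set(t.index[t["significant"]]) for name, t in tables.items()}
    pathways = sorted(set().union(*enriched.values()))
    columns = pd.MultiIndex.from_product([list(tables), ["neg_log10_p", "direction_z"]])
    wide = pd.DataFrame(index=pathways, columns=columns, dtype=float)
    for name, t in tables.items():
        present = [p for p in pathways if p in t.index]
        wide.loc[present, (name, "neg_log10_p")] = t.loc[present, "neg_log10_p"].to_numpy()
        wide.loc[present, (name, "direction_z")] = t.loc[present, "direction_z"].to_numpy()

    overlap = sorted(enriched[pair[0]] & enriched[pair[1]])
    return OverlapTable(wide, tuple(pair), overlap)


def shared_gene_report(
    de_lists: Mapping[str, set[str]],
    pathways: Sequence[str],
    collection: GeneSetCollection,
) -> tuple[dict[str, set[str]], set[str]]:
    """Genes differential in every experiment and inside each overlap pathway.

    Returns (per-pathway shared-gene sets, union across pathways); the union
    counts each gene once even when pathways share members.
    """
    shared_de = set.intersection(*[set(v) for v in de_lists.values()])
    per_pathway = {p: shared_de & collection.sets[p] for p in pathways}
    union = set().union(*per_pathway.values()) if per_pathway else set()
    return per_pathway, union
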
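"""End-to-end demonstration pipeline on simulated data.

Mirrors the full study design on a synthetic cohort with known ground
truth:

1. genetics — a four-group cohort (19 EA/BE, 44 EA-only, 10 BE-only,
   730 controls) is simulated at a 30-SNP Barrett's-risk panel with the
   case group's allele frequencies elevated; polygenic scores are computed
   under literature and in-sample OR weights and compared nonparametrically,
   and per-SNP allele association is estimated between patient subgroups.
2. biopsy transcriptome — an 11-vs-10 GEJ-biopsy-style count matrix with
   planted pathway-level effects; three-criterion DE filter + enrichment.
3. fibroblast acid exposure — a four-condition (patient/control x
   exposed/unexposed) matrix; the exposed contrast's DE genes are cleaned
   by subtracting the unexposed (baseline) contrast's DE genes, and both
   the biopsy and fibroblast enrichment tables feed a cross-experiment
   pathway-overlap report with a shared-gene list.

All randomness derives from one integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import (
    GeneSetCollection,
    overlap_experiments,
    overrepresentation,
    shared_gene_report,
)
from .expression import DifferentialExpressionModel, subtract_baseline
from .pgrs import PolygenicScoreModel, estimate_insample_ors, write_score_table
from .simulate import (
    ExpressionSimConfig,
    PlantedEffect,
    default_genotype_config,
    simulate_counts,
    simulate_genotypes,
)

__all__ = ["run_demo", "demo_pathway_collection"]

PATIENT_GROUPS = ["EA/BE", "EA-only", "BE-only"]
ALL_GROUPS = PATIENT_GROUPS + ["control"]

_N_GENES = 4000
_N_PATHWAYS = 25
_PATHWAY_SIZE = 40


def demo_pathway_collection(seed: int) -> GeneSetCollection:
    """Disjoint named gene sets over the shared demo gene namespace."""
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(_N_GENES)]
    chosen = rng.choice(genes, size=_N_PATHWAYS * _PATHWAY_SIZE, replace=False)
    sets = {
        f"pathway_{i:02d}": set(chosen[i * _PATHWAY_SIZE : (i + 1) * _PATHWAY_SIZE])
        for i in range(_N_PATHWAYS)
    }
    return GeneSetCollection(sets, universe=set(genes))


def _members(collection: GeneSetCollection, names: list[str], frac: float, rng) -> list[str]:
    picked: list[str] = []
    for name in names:
        members = sorted(collection.sets[name])
        k = int(len(members) * frac)
        picked += list(rng.choice(members, size=k, replace=False))
    return picked


def _expression_configs(seed: int, collection: GeneSetCollection):
    """Biopsy and fibroblast simulation configs sharing pathway structure.

    Pathways 0-4 respond in the biopsy contrast; 0-2 and 5-6 respond to
    acid in patient fibroblasts; 7-8 differ constitutively between patient
    and control fibroblasts (and are therefore subtracted as baseline
    signal).  Pathways 0-2 are the designed cross-experiment overlap.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(collection.universe)

    biopsy_de = _members(collection, [f"pathway_{i:02d}" for i in range(5)], 0.6, rng)
    biopsy_de += list(rng.choice([g for g in genes if g not in set(biopsy_de)], size=60, replace=False))

    acid_de = _members(collection, [f"pathway_{i:02d}" for i in (0, 1, 2, 5, 6)], 0.6, rng)
    acid_de += list(rng.choice([g for g in genes if g not in set(acid_de)], size=60, replace=False))

    constitutive = _members(collection, [f"pathway_{i:02d}" for i in (7, 8)], 0.6, rng)

    lengths = [int(x) for x in rng.integers(500, 5000, size=len(genes))]
    plan = {name: sorted(members) for name, members in collection.sets.items()}

    def split(pool: list[str]) -> tuple[tuple[str, ...], tuple[str, ...]]:
        half = len(pool) // 2
        return tuple(pool[:half]), tuple(pool[half:])

    b_up, b_down = split(biopsy_de)
    biopsy_cfg = ExpressionSimConfig(
        n_genes=_N_GENES,
        conditions=(("EA/BE", 11), ("BE-only", 10)),
        gene_lengths=lengths,
        dispersion=0.1,
        effects=[
            PlantedEffect(b_up, 3.0, "up", "EA/BE"),
            PlantedEffect(b_down, 3.0, "down", "EA/BE"),
        ],
        pathway_plan=plan,
        seed=seed + 11,
    )

    a_up, a_down = split(acid_de)
    c_up, c_down = split(constitutive)
    fibro_effects = [
        PlantedEffect(a_up, 4.0, "up", "patient-exposed"),
        PlantedEffect(a_down, 4.0, "down", "patient-exposed"),
        # constitutive patient-vs-control differences show up in both contrasts
        PlantedEffect(c_up, 4.0, "up", "patient-exposed"),
        PlantedEffect(c_up, 4.0, "up", "patient-unexposed"),
        PlantedEffect(c_down, 4.0, "down", "patient-exposed"),
        PlantedEffect(c_down, 4.0, "down", "patient-unexposed"),
    ]
    # cultured fibroblast replicates are far less dispersed than patient
    # biopsies; acid exposure is a drastic perturbation
    fibro_cfg = ExpressionSimConfig(
        n_genes=_N_GENES,
        conditions=(
            ("patient-exposed", 3),
            ("control-exposed", 3),
            ("patient-unexposed", 3),
            ("control-unexposed", 3),
        ),
        gene_lengths=lengths,
        dispersion=0.01,
        effects=fibro_effects,
        pathway_plan=plan,
        seed=seed + 12,
    )
    return biopsy_cfg, fibro_cfg


def run_demo(seed: int, outdir: str | Path | None = None) -> dict:
    """Run the full simulated pipeline; optionally write all stage outputs.

    Returns a JSON-serializable dict of the headline quantities each stage
    computed.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- genetics -----------------------------------------------------
    cohort, truth = simulate_genotypes(default_genotype_config(seed))
    lit = PolygenicScoreModel(cohort, or_source="literature").fit(compare=ALL_GROUPS)
    insample = PolygenicScoreModel(
        cohort, or_source="in_sample", case_group="EA/BE", control_group="control"
    ).fit(compare=ALL_GROUPS)
    subgroup_assoc = estimate_insample_ors(cohort, "EA/BE", "BE-only")

    # --- biopsy + fibroblast transcriptomes ---------------------------
    collection = demo_pathway_collection(seed + 10)
    biopsy_cfg, fibro_cfg = _expression_configs(seed + 20, collection)

    biopsy, _ = simulate_counts(biopsy_cfg)
    biopsy_res = DifferentialExpressionModel(biopsy, "EA/BE", "BE-only").fit()
    biopsy_dirs = biopsy_res.table.loc[biopsy_res.table["pass"], "direction"].to_dict()
    biopsy_enr = overrepresentation(biopsy_res.de_genes, collection, biopsy_dirs)

    fibro, _ = simulate_counts(fibro_cfg)
    exposed_res = DifferentialExpressionModel(fibro, "patient-exposed", "control-exposed").fit()
    baseline_res = DifferentialExpressionModel(fibro, "patient-unexposed", "control-unexposed").fit()
    subtraction = subtract_baseline(exposed_res.de_genes, baseline_res.de_genes)
    fibro_dirs = exposed_res.table.loc[exposed_res.table["pass"], "direction"].to_dict()
    fibro_enr = overrepresentation(exposed_res.de_genes, collection, fibro_dirs)

    overlap = overlap_experiments(
        {"biopsy": biopsy_enr, "fibroblast": fibro_enr}, ("biopsy", "fibroblast")
    )
    per_pathway, shared_union = shared_gene_report(
        {"biopsy": biopsy_res.de_genes, "fibroblast": exposed_res.de_genes},
        overlap.overlap_pathways,
        collection,
    )

    med_lit = lit.median_by_group()
    med_ins = insample.median_by_group()
    results = {
        "seed": seed,
        "pgrs": {
            "median_literature": {g: float(med_lit[g]) for g in ALL_GROUPS},
            "median_in_sample": {g: float(med_ins[g]) for g in ALL_GROUPS},
            "kruskal_wallis_p_literature": lit.comparison.omnibus_p,
            "kruskal_wallis_p_in_sample": insample.comparison.omnibus_p,
        },
        "association": {
            "n_snps": int(len(subgroup_assoc)),
            "n_nominal": int((subgroup_assoc["p_value"] < 0.05).sum()),
        },
        "biopsy": {
            "n_expressed": len(biopsy_res.expressed_genes),
            "n_de": len(biopsy_res.de_genes),
            "n_enriched_pathways": int(biopsy_enr["significant"].sum()),
        },
        "fibroblast": {
            "n_expressed": len(exposed_res.expressed_genes),
            "n_de_exposed": subtraction.n_exposed,
            "n_de_baseline": subtraction.n_baseline,
            "n_after_subtraction": subtraction.n_remaining,
            "n_enriched_pathways": int(fibro_enr["significant"].sum()),
        },
        "overlap": {
            "n_overlap_pathways": overlap.n_overlap,
            "pathways": overlap.overlap_pathways,
            "n_shared_genes": len(shared_union),
        },
    }

    if out is not None:
        write_score_table(lit.scores, out / "pgrs_literature.tsv")
        write_score_table(insample.scores, out / "pgrs_in_sample.tsv")
        lit.comparison.to_json(out / "comparison_literature.json")
        insample.comparison.to_json(out / "comparison_in_sample.json")
        subgroup_assoc.to_csv(out / "association_EABE_vs_BEonly.tsv", sep="\t", float_format="%.6g")
        biopsy_res.write(out / "de_biopsy.tsv")
        exposed_res.write(out / "de_fibroblast_exposed.tsv")
        baseline_res.write(out / "de_fibroblast_baseline.tsv")
        with (out / "subtraction.json").open("w") as fh:
            json.dump(
                {
                    "n_exposed": subtraction.n_exposed,
                    "n_baseline": subtraction.n_baseline,
                    "n_intersection": subtraction.n_intersection,
                    "n_remaining": subtraction.n_remaining,
                    "remaining": sorted(subtraction.remaining),
                },
                fh,
                indent=2,
            )
        biopsy_enr.to_csv(out / "enrichment_biopsy.tsv", sep="\t", float_format="%.6g")
        fibro_enr.to_csv(out / "enrichment_fibroblast.tsv", sep="\t", float_format="%.6g")
        overlap.write(out / "overlap.tsv")
        with (out / "shared_genes.json").open("w") as fh:
            json.dump(
                {p: sorted(g) for p, g in per_pathway.items()} | {"union": sorted(shared_union)},
                fh,
                indent=2,
            )
        with (out / "demo_results.json").open("w") as fh:
            json.dump(results, fh, indent=2)
            fh.write("\n")
    return results
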
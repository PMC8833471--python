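"""Risk-locus tables, cohort genotypes and allele harmonization.

A susceptibility panel is a small set of literature-curated lead (or proxy)
SNPs, each with a declared risk allele and a published odds ratio.  Cohort
genotypes arrive either as a VCF or as a tabular sample x SNP dosage matrix;
either way each genotype is reduced to a *risk-allele dosage* in {0, 1, 2}
(count of risk alleles carried), the quantity the additive polygenic score
is built from.

Because the risk allele is declared on an arbitrary strand/orientation by
the source GWAS, every locus is harmonized against the VCF REF/ALT pair
before counting: alleles may match as-is, be swapped (risk allele == REF),
or sit on the opposite strand.  Palindromic pairs (A/T, C/G) cannot be
strand-resolved without frequency heuristics and are dropped by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RiskLocus",
    "GenotypeMatrix",
    "HarmonizationOutcome",
    "HarmonizationReport",
    "read_risk_table",
    "write_risk_table",
    "harmonize_locus",
    "read_genotypes_vcf",
    "read_dosage_table",
    "write_dosage_table",
    "read_group_map",
]

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class RiskLocus:
    """One literature risk SNP with its risk allele and published OR weight."""

    snp_id: str
    risk_allele: str
    other_allele: str
    published_or: float
    phenotype_tag: str = "combined"
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.risk_allele not in _VALID_BASES:
            raise ValueError(
                f"{self.snp_id}: risk allele {self.risk_allele!r} is not one of A,C,G,T"
            )
        if self.other_allele not in _VALID_BASES:
            raise ValueError(
                f"{self.snp_id}: other allele {self.other_allele!r} is not one of A,C,G,T"
            )
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: risk and other allele are identical")
        if not np.isfinite(self.published_or) or self.published_or <= 0:
            raise ValueError(
                f"{self.snp_id}: odds ratio must be a positive real, got {self.published_or}"
            )

    @property
    def log_or(self) -> float:
        return float(np.log(self.published_or))

    def flipped(self) -> "RiskLocus":
        """The same locus with allele labels exchanged and the OR inverted."""
        return RiskLocus(
            snp_id=self.snp_id,
            risk_allele=self.other_allele,
            other_allele=self.risk_allele,
            published_or=1.0 / self.published_or,
            phenotype_tag=self.phenotype_tag,
            source_tag=self.source_tag,
        )


class HarmonizationOutcome(str, Enum):
    MATCHED_AS_IS = "matched_as_is"
    ALLELE_SWAPPED = "allele_swapped"
    STRAND_FLIPPED = "strand_flipped"
    AMBIGUOUS_DROPPED = "ambiguous_dropped"
    NOT_FOUND = "not_found"


@dataclass
class HarmonizationReport:
    """Per-locus harmonization outcomes plus missing-genotype counts.

    Outcomes partition the input panel: every locus appears exactly once.
    """

    outcome: dict[str, HarmonizationOutcome] = field(default_factory=dict)
    n_missing: dict[str, int] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        tally = {o.value: 0 for o in HarmonizationOutcome}
        for o in self.outcome.values():
            tally[o.value] += 1
        return tally

    def usable_loci(self) -> list[str]:
        usable = {
            HarmonizationOutcome.MATCHED_AS_IS,
            HarmonizationOutcome.ALLELE_SWAPPED,
            HarmonizationOutcome.STRAND_FLIPPED,
        }
        return [s for s, o in self.outcome.items() if o in usable]


class GenotypeMatrix:
    """Sample x locus risk-allele dosages with per-sample group labels.

    Dosages live in a float DataFrame with values in {0, 1, 2} and NaN for
    missing genotypes; columns follow the locus panel order.
    """

    def __init__(
        self,
        dosage: pd.DataFrame,
        loci: Sequence[RiskLocus],
        group_of: Mapping[str, str],
    ) -> None:
        loci = list(loci)
        locus_ids = [l.snp_id for l in loci]
        if list(dosage.columns) != locus_ids:
            raise ValueError("dosage columns must match the locus panel (id and order)")
        values = dosage.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = sorted(set(values[~ok].tolist()))
            raise ValueError(f"dosage values restricted to 0/1/2/missing, found {bad}")
        missing = [s for s in dosage.index if s not in group_of]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.dosage = dosage.astype(float)
        self.loci = loci
        self.group_of = pd.Series({s: group_of[s] for s in dosage.index}, name="group")

    @property
    def samples(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def locus_ids(self) -> list[str]:
        return [l.snp_id for l in self.loci]

    def locus(self, snp_id: str) -> RiskLocus:
        for l in self.loci:
            if l.snp_id == snp_id:
                return l
        raise KeyError(snp_id)

    def subset_loci(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        keep = [l for l in self.loci if l.snp_id in set(snp_ids)]
        return GenotypeMatrix(
            self.dosage[[l.snp_id for l in keep]], keep, self.group_of.to_dict()
        )

    def flipped(self) -> "GenotypeMatrix":
        """Allele-label flip: every dosage d becomes 2 - d (missing stays missing)."""
        return GenotypeMatrix(
            2.0 - self.dosage, [l.flipped() for l in self.loci], self.group_of.to_dict()
        )


# ---------------------------------------------------------------------------
# risk-table I/O

_RISK_COLUMNS = ["snp_id", "risk_allele", "other_allele", "or", "phenotype", "source"]


def read_risk_table(path: str | Path) -> list[RiskLocus]:
    """Read a tab-delimited risk-locus table.

    Required header columns: snp_id, risk_allele, other_allele, or; optional:
    phenotype, source.  Row order is preserved; duplicate snp_ids and
    non-positive odds ratios are rejected with the offending line named.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"snp_id", "risk_allele", "other_allele", "or"}
        if not required.issubset(header):
            raise ValueError(
                f"{path}: header must contain {sorted(required)}, got {header}"
            )
        idx = {name: header.index(name) for name in header}
        loci: list[RiskLocus] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path} line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            snp_id = fields[idx["snp_id"]]
            try:
                or_value = float(fields[idx["or"]])
            except ValueError as exc:
                raise ValueError(
                    f"{path} line {lineno} ({snp_id}): unparseable odds ratio "
                    f"{fields[idx['or']]!r}"
                ) from exc
            if snp_id in seen:
                raise ValueError(f"{path} line {lineno}: duplicate snp_id {snp_id}")
            seen.add(snp_id)
            try:
                locus = RiskLocus(
                    snp_id=snp_id,
                    risk_allele=fields[idx["risk_allele"]].upper(),
                    other_allele=fields[idx["other_allele"]].upper(),
                    published_or=or_value,
                    phenotype_tag=fields[idx["phenotype"]] if "phenotype" in idx else "combined",
                    source_tag=fields[idx["source"]] if "source" in idx else "",
                )
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
            loci.append(locus)
    return loci


def write_risk_table(loci: Iterable[RiskLocus], path: str | Path) -> None:
    rows = [
        (l.snp_id, l.risk_allele, l.other_allele, repr(l.published_or), l.phenotype_tag, l.source_tag)
        for l in loci
    ]
    with Path(path).open("w") as fh:
        fh.write("\t".join(_RISK_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# harmonization


def _is_palindromic(a: str, b: str) -> bool:
    return {a, b} in _PALINDROMIC


def harmonize_locus(
    vcf_ref: str,
    vcf_alt: str,
    locus: RiskLocus,
    allow_ambiguous: bool = False,
) -> HarmonizationOutcome:
    """Classify how a VCF REF/ALT pair maps onto a declared risk/other pair.

    ``matched_as_is``    REF == other allele, ALT == risk allele
    ``allele_swapped``   REF == risk allele, ALT == other allele
    ``strand_flipped``   the reverse-complemented VCF pair matches either way
    ``ambiguous_dropped``palindromic A/T or C/G pair (strand unresolvable)
    ``not_found``        alleles incompatible with the declared pair
    """
    vcf_ref, vcf_alt = vcf_ref.upper(), vcf_alt.upper()
    for allele in (vcf_ref, vcf_alt):
        if allele not in _VALID_BASES:
            raise ValueError(f"non-ACGT allele {allele!r} at {locus.snp_id}")
    if _is_palindromic(vcf_ref, vcf_alt) and not allow_ambiguous:
        return HarmonizationOutcome.AMBIGUOUS_DROPPED
    risk, other = locus.risk_allele, locus.other_allele
    if (vcf_ref, vcf_alt) == (other, risk):
        return HarmonizationOutcome.MATCHED_AS_IS
    if (vcf_ref, vcf_alt) == (risk, other):
        return HarmonizationOutcome.ALLELE_SWAPPED
    flipped = (_COMPLEMENT[vcf_ref], _COMPLEMENT[vcf_alt])
    if flipped == (other, risk) or flipped == (risk, other):
        return HarmonizationOutcome.STRAND_FLIPPED
    return HarmonizationOutcome.NOT_FOUND


def _dosage_from_outcome(
    outcome: HarmonizationOutcome,
    alt_count: float,
    vcf_ref: str,
    vcf_alt: str,
    locus: RiskLocus,
) -> float:
    """Risk-allele dosage given the harmonization outcome and the ALT count."""
    if np.isnan(alt_count):
        return np.nan
    if outcome is HarmonizationOutcome.MATCHED_AS_IS:
        return alt_count
    if outcome is HarmonizationOutcome.ALLELE_SWAPPED:
        return 2.0 - alt_count
    if outcome is HarmonizationOutcome.STRAND_FLIPPED:
        # after complementing, ALT may land on either declared allele
        if _COMPLEMENT[vcf_alt] == locus.risk_allele:
            return alt_count
        return 2.0 - alt_count
    raise ValueError(f"no dosage for outcome {outcome}")


def read_genotypes_vcf(
    path: str | Path,
    loci: Sequence[RiskLocus],
    group_of: Mapping[str, str],
    allow_ambiguous: bool = False,
) -> tuple[GenotypeMatrix, HarmonizationReport]:
    """Extract harmonized risk-allele dosages for a locus panel from a VCF.

    Loci are matched by ID.  Multiallelic records and loci absent from the
    VCF are reported ``not_found`` and excluded from the returned matrix.
    Samples present in the VCF but absent from ``group_of`` raise at matrix
    construction (the downstream join), per the I/O contract.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    report = HarmonizationReport()
    columns: dict[str, np.ndarray] = {}
    kept: list[RiskLocus] = []
    by_id = {l.snp_id: l for l in loci}
    seen: set[str] = set()

    for record in vcf:
        rid = record.ID
        if rid is None or rid not in by_id or rid in seen:
            continue
        seen.add(rid)
        locus = by_id[rid]
        if len(record.ALT) != 1 or len(record.REF) != 1 or len(record.ALT[0]) != 1:
            report.outcome[rid] = HarmonizationOutcome.NOT_FOUND
            warnings.warn(f"{rid}: multiallelic or non-SNP record skipped")
            continue
        outcome = harmonize_locus(record.REF, record.ALT[0], locus, allow_ambiguous)
        if outcome is HarmonizationOutcome.AMBIGUOUS_DROPPED and allow_ambiguous:
            outcome = HarmonizationOutcome.MATCHED_AS_IS
        report.outcome[rid] = outcome
        if outcome in (
            HarmonizationOutcome.AMBIGUOUS_DROPPED,
            HarmonizationOutcome.NOT_FOUND,
        ):
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = record.gt_types.astype(float)
        alt_count = np.where(gt == 3, 2.0, np.where(gt == 1, 1.0, np.where(gt == 0, 0.0, np.nan)))
        dosage = np.array(
            [
                _dosage_from_outcome(outcome, ac, record.REF, record.ALT[0], locus)
                for ac in alt_count
            ]
        )
        columns[rid] = dosage
        report.n_missing[rid] = int(np.isnan(dosage).sum())
        kept.append(locus)

    for locus in loci:
        if locus.snp_id not in report.outcome:
            report.outcome[locus.snp_id] = HarmonizationOutcome.NOT_FOUND
            warnings.warn(f"{locus.snp_id}: not found in VCF, excluded from scoring")

    dosage = pd.DataFrame(
        {l.snp_id: columns[l.snp_id] for l in kept}, index=samples, dtype=float
    )
    return GenotypeMatrix(dosage, kept, group_of), report


# ---------------------------------------------------------------------------
# tabular dialects


def read_dosage_table(
    path: str | Path, loci: Sequence[RiskLocus], group_of: Mapping[str, str]
) -> GenotypeMatrix:
    """Read the tabular dosage dialect: sample_id column then one column per
    snp_id, cells in {0,1,2,NA}."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    df.index.name = None
    locus_ids = [l.snp_id for l in loci]
    missing = [s for s in locus_ids if s not in df.columns]
    if missing:
        raise ValueError(f"{path}: dosage table lacks panel loci {missing}")
    return GenotypeMatrix(df[locus_ids].astype(float), loci, group_of)


def write_dosage_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    out = matrix.dosage.copy()
    # dosages are integral; render without a decimal point, NA for missing
    formatted = out.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    formatted.index.name = "sample_id"
    formatted.to_csv(path, sep="\t")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column tab-delimited sample_id -> group label map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"], dtype=str)
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate sample ids {sorted(set(dup))}")
    return dict(zip(df["sample_id"], df["group"]))


def write_group_map(group_of: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sample, group in group_of.items():
            fh.write(f"{sample}\t{group}\n")
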
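"""Cohort container: subjects, phenotype labels and the dosage matrix.

Genotypes are stored as risk-allele dosage — 0 for homozygous other
allele, 1 for heterozygous, 2 for homozygous risk allele — in a float
matrix with ``NaN`` marking missing calls.  Missing calls stay in the
matrix and are dropped test-wise (complete-case per SNP) by the analysis
modules.

File dialect
------------
Genotypes: tab-separated, header ``subject_id`` followed by rsIDs, calls
written ``X/Y`` with ``./.`` for missing.  Phenotypes: tab-separated with
``subject_id``, ``group`` (control | CD), ``site`` (L1 | L2 | L3 | none)
and optional covariate columns (sex, age_at_diagnosis_years, smoking,
behavior, familial_cd, surgical_presentation, perianal, upper_gi).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import SnpPanel, SnpPanelEntry

logger = logging.getLogger(__name__)

MISSING_CALL = "./."
GROUPS = ("control", "CD")
SITES = ("L1", "L2", "L3", "none")
CD_SITES = ("L1", "L2", "L3")

#: covariate columns recognised in phenotype files, in output order
COVARIATE_COLUMNS = (
    "sex",
    "gender",
    "age_at_diagnosis_years",
    "smoking",
    "behavior",
    "familial_cd",
    "surgical_presentation",
    "perianal",
    "upper_gi",
)


class CohortError(ValueError):
    """Inconsistent genotype/phenotype input."""


@dataclass
class SubjectRecord:
    """Phenotype record for one subject.

    ``site`` is the Montreal disease-location label: L1 ileal, L2
    colonic, L3 ileocolonic; controls carry ``none``.  ``upper_gi`` is
    the L4 (upper digestive tract) modifier.
    """

    subject_id: str
    group: str
    site: str = "none"
    covariates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(
                f"subject {self.subject_id}: group {self.group!r} not in {GROUPS}"
            )
        if self.site not in SITES:
            raise CohortError(
                f"subject {self.subject_id}: site {self.site!r} not in {SITES}"
            )
        if self.group == "control" and self.site != "none":
            raise CohortError(
                f"subject {self.subject_id}: control subjects must have site 'none'"
            )
        if self.group == "CD" and self.site not in CD_SITES:
            raise CohortError(
                f"subject {self.subject_id}: CD subjects need site L1, L2 or L3"
            )


class Cohort:
    """Subjects x SNPs risk-allele dosage matrix with group/site labels."""

    def __init__(self, subjects: list[SubjectRecord], panel: SnpPanel, dosage: np.ndarray):
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(subjects), len(panel)):
            raise CohortError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(subjects)} subjects x {len(panel)} SNPs"
            )
        valid = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = dosage[~valid].flat[0]
            raise CohortError(f"dosage values must be 0, 1, 2 or NaN (found {bad!r})")
        self.subjects = list(subjects)
        self.panel = panel
        self.dosage = dosage

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def group_mask(self, groups: tuple[str, ...] | str) -> np.ndarray:
        """Boolean mask selecting subjects by group or site label.

        Accepted labels: ``control``, ``CD`` (all cases) or a Montreal
        site ``L1``/``L2``/``L3``.
        """
        if isinstance(groups, str):
            groups = (groups,)
        mask = np.zeros(self.n_subjects, dtype=bool)
        for g in groups:
            if g == "control":
                mask |= np.array([s.group == "control" for s in self.subjects])
            elif g == "CD":
                mask |= np.array([s.group == "CD" for s in self.subjects])
            elif g in CD_SITES:
                mask |= np.array([s.site == g for s in self.subjects])
            else:
                raise CohortError(f"unknown group selector {g!r}")
        return mask

    def dosages_for(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self.panel.index_of(snp_id)]

    def present_sites(self) -> set[str]:
        return {s.site for s in self.subjects if s.group == "CD"}


def encode_dosage(genotype_call: str, entry: SnpPanelEntry) -> float:
    """Risk-allele count for one ``X/Y`` call; ``./.`` gives NaN.

    Symmetric in allele order: ``C/T`` and ``T/C`` encode identically.
    Raises :class:`CohortError` if an allele is neither the risk nor the
    other allele of the panel entry.
    """
    call = genotype_call.strip()
    if call == MISSING_CALL or call == "":
        return float("nan")
    parts = call.split("/")
    if len(parts) != 2:
        raise CohortError(f"{entry.snp_id}: malformed genotype call {call!r}")
    n_risk = 0
    for allele in parts:
        a = allele.strip().upper()
        if a == entry.risk_allele:
            n_risk += 1
        elif a != entry.other_allele:
            raise CohortError(
                f"{entry.snp_id}: allele {a!r} is neither risk "
                f"({entry.risk_allele}) nor other ({entry.other_allele})"
            )
    return float(n_risk)


def decode_dosage(dosage: float, entry: SnpPanelEntry) -> str:
    """Inverse of :func:`encode_dosage` with a canonical allele order."""
    if np.isnan(dosage):
        return MISSING_CALL
    d = int(dosage)
    return {
        0: f"{entry.other_allele}/{entry.other_allele}",
        1: f"{entry.risk_allele}/{entry.other_allele}",
        2: f"{entry.risk_allele}/{entry.risk_allele}",
    }[d]


def _read_phenotypes(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise CohortError(f"{path}: phenotype file lacks column {col!r}")
    records = []
    for _, row in df.iterrows():
        cov = {
            c: row[c]
            for c in COVARIATE_COLUMNS
            if c in df.columns and str(row[c]) != ""
        }
        records.append(
            SubjectRecord(
                subject_id=row["subject_id"],
                group=row["group"],
                site=row.get("site", "") or "none",
                covariates=cov,
            )
        )
    return records


def load_cohort(
    genotype_path: str | Path, phenotype_path: str | Path, panel: SnpPanel
) -> Cohort:
    """Assemble a :class:`Cohort` from genotype + phenotype TSVs.

    Subject ids must match 1:1 between the two files; genotype columns
    must all be panel SNPs.  Per-SNP missingness is logged at info level.
    """
    subjects = _read_phenotypes(phenotype_path)
    geno = pd.read_csv(genotype_path, sep="\t", dtype=str)
    if "subject_id" not in geno.columns:
        raise CohortError(f"{genotype_path}: genotype file lacks 'subject_id'")
    unknown = [c for c in geno.columns[1:] if c not in panel]
    if unknown:
        raise CohortError(
            f"{genotype_path}: genotype columns not in panel: {', '.join(unknown)}"
        )
    geno_ids = list(geno["subject_id"])
    pheno_ids = [s.subject_id for s in subjects]
    only_geno = sorted(set(geno_ids) - set(pheno_ids))
    only_pheno = sorted(set(pheno_ids) - set(geno_ids))
    if only_geno or only_pheno:
        raise CohortError(
            "subject ids do not match 1:1 "
            f"(genotypes only: {only_geno[:5]}; phenotypes only: {only_pheno[:5]})"
        )
    geno = geno.set_index("subject_id").loc[pheno_ids]
    dosage = np.full((len(subjects), len(panel)), np.nan)
    for j, entry in enumerate(panel):
        if entry.snp_id not in geno.columns:
            continue  # SNP absent from file: stays all-missing
        col = geno[entry.snp_id].fillna(MISSING_CALL)
        for i, call in enumerate(col):
            try:
                dosage[i, j] = encode_dosage(call, entry)
            except CohortError as err:
                raise CohortError(f"subject {pheno_ids[i]}: {err}") from None
        miss = np.isnan(dosage[:, j]).mean()
        if miss:
            logger.info("%s: %.1f%% missing calls", entry.snp_id, 100 * miss)
    return Cohort(subjects, panel, dosage)


def write_cohort(
    cohort: Cohort, genotype_path: str | Path, phenotype_path: str | Path
) -> None:
    """Write the cohort back out in the TSV dialect (lossless round-trip)."""
    with open(genotype_path, "w") as fh:
        fh.write("subject_id\t" + "\t".join(cohort.panel.snp_ids) + "\n")
        for i, s in enumerate(cohort.subjects):
            calls = [
                decode_dosage(cohort.dosage[i, j], entry)
                for j, entry in enumerate(cohort.panel)
            ]
            fh.write(s.subject_id + "\t" + "\t".join(calls) + "\n")
    used_cov = [
        c
        for c in COVARIATE_COLUMNS
        if any(c in s.covariates for s in cohort.subjects)
    ]
    with open(phenotype_path, "w") as fh:
        fh.write("\t".join(["subject_id", "group", "site", *used_cov]) + "\n")
        for s in cohort.subjects:
            row = [s.subject_id, s.group, s.site]
            row += [s.covariates.get(c, "") for c in used_cov]
            fh.write("\t".join(row) + "\n")


def load_genotypes_vcf(path: str | Path, panel: SnpPanel) -> pd.DataFrame:
    """Read genotype calls from a VCF, matched to the panel by variant ID.

    Returns a subjects x SNPs DataFrame of calls in the ``X/Y`` dialect
    (positions are ignored; REF/ALT must agree with the panel's allele
    pair).  Requires cyvcf2.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: dict[str, list[str]] = {}
    for variant in vcf:
        if variant.ID not in panel:
            continue
        entry = panel[variant.ID]
        alleles = {variant.REF, *variant.ALT}
        if not alleles <= {entry.risk_allele, entry.other_allele}:
            raise CohortError(
                f"{variant.ID}: VCF alleles {sorted(alleles)} disagree with panel "
                f"({entry.risk_allele}/{entry.other_allele})"
            )
        col = []
        for gt in variant.genotypes:
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                col.append(MISSING_CALL)
            else:
                lookup = [variant.REF, *variant.ALT]
                col.append(f"{lookup[a]}/{lookup[b]}")
        calls[variant.ID] = col
    df = pd.DataFrame(calls, index=samples)
    df.index.name = "subject_id"
    return df


def raf_to_allele_counts(raf: float, n_subjects: int) -> int:
    """Risk-allele count out of ``2 * n_subjects`` chromosomes.

    Nearest-integer reconstruction from a printed frequency; approximate
    because published frequencies carry only two decimals.
    """
    if not 0.0 <= raf <= 1.0:
        raise ValueError(f"raf must be in [0, 1], got {raf}")
    if n_subjects < 0:
        raise ValueError("n_subjects must be >= 0")
    return int(math.floor(2 * n_subjects * raf + 0.5))


def round_half_up(x: float) -> int:
    """Integer rounding with .5 going up (the convention of printed tables)."""
    return int(math.floor(x + 0.5))


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Counts and integer percentages of CD covariates, overall and by site.

    Mirrors a standard clinical-characteristics table: one block per
    categorical covariate, columns for the whole CD cohort and each
    Montreal site.  Subjects with a missing value are listed in a
    ``missing`` row and excluded from the percentage denominator.
    """
    if cohort.n_subjects == 0:
        raise CohortError("empty cohort")
    cd = [s for s in cohort.subjects if s.group == "CD"]
    groups: dict[str, list[SubjectRecord]] = {"all": cd}
    for site in CD_SITES:
        groups[site] = [s for s in cd if s.site == site]
    covs: list[str] = []
    for s in cd:
        for c in s.covariates:
            if c != "age_at_diagnosis_years" and c not in covs:
                covs.append(c)
    rows = []
    for cov in covs:
        for gname, members in groups.items():
            values = [s.covariates.get(cov, "") for s in members]
            present = [v for v in values if v not in ("", "missing")]
            n_missing = len(values) - len(present)
            denom = len(present)
            for cat in sorted(set(present)):
                n = present.count(cat)
                pct = round_half_up(100 * n / denom) if denom else 0
                rows.append((cov, cat, gname, n, pct))
            if n_missing:
                rows.append((cov, "missing", gname, n_missing, None))
    return pd.DataFrame(rows, columns=["covariate", "category", "group", "n", "pct"])
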
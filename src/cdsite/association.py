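"""Case-control association battery.

For each marker and each comparison stratum this module builds a 2x2
table — risk vs other allele counts under the *allelic* model (each
subject contributes two chromosomes) or carrier (dosage >= 1) vs
non-carrier subjects under the *carrier* (dominant) model — and tests it
with Pearson's chi-square, falling back to the two-sided Fisher exact
test whenever any expected cell is below 5 (Cochran's rule).  Odds
ratios carry Woolf log-scale 95% confidence intervals, with the
Haldane–Anscombe 0.5 correction applied to the OR/CI (never to the test
statistic) when a cell is empty.

Multiple testing is controlled family-wise by Bonferroni over the number
of *loci*, not SNPs: with the bundled 19-locus panel the threshold is
0.05/19 ≈ 2.6e-3.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .fixtures import PrintedTableFixture

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # Phi^-1(0.975)

#: the seven comparison strata: all-CD vs controls, each Montreal site vs
#: controls, and the three site-vs-site contrasts
COMPARISONS: dict[str, tuple[str, str]] = {
    "CD_vs_ctrl": ("CD", "control"),
    "L1_vs_ctrl": ("L1", "control"),
    "L2_vs_ctrl": ("L2", "control"),
    "L3_vs_ctrl": ("L3", "control"),
    "L1_vs_L2": ("L1", "L2"),
    "L3_vs_L2": ("L3", "L2"),
    "L3_vs_L1": ("L3", "L1"),
}

#: the three common NOD2 coding variants pooled into the composite marker
NOD2_SNPS = ("rs2066844", "rs2066845", "rs2066847")


@dataclass(frozen=True)
class Comparison:
    """One case-group vs reference-group contrast."""

    label: str
    case_group: str
    reference_group: str

    @classmethod
    def from_label(cls, label: str) -> "Comparison":
        if label not in COMPARISONS:
            raise ValueError(
                f"unknown comparison {label!r}; expected one of {tuple(COMPARISONS)}"
            )
        case, ref = COMPARISONS[label]
        return cls(label, case, ref)


@dataclass
class AssociationResult:
    """Outcome of one 2x2 test: marker x comparison x genetic model."""

    marker_id: str
    comparison: str
    model: str  # "allelic" | "carrier"
    a: int  # case risk / case carriers
    b: int  # case other / case non-carriers
    c: int  # ref risk / ref carriers
    d: int  # ref other / ref non-carriers
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    test_used: str  # "chi2" | "fisher" | "none"
    composite: bool = False
    untestable: bool = False
    nominal_significant: bool = False
    bonferroni_significant: bool = False


class CompositeMarker:
    """Any-member carrier indicator over a set of panel SNPs."""

    def __init__(self, marker_id: str, member_snp_ids: tuple[str, ...] = NOD2_SNPS):
        if not member_snp_ids:
            raise ValueError("composite marker needs at least one member SNP")
        self.marker_id = marker_id
        self.member_snp_ids = tuple(member_snp_ids)


def hwe_test(n_hom_risk: int, n_het: int, n_hom_other: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit to Hardy–Weinberg proportions.

    Expected genotype counts come from the sample allele frequency.
    Monomorphic samples are in trivial equilibrium and return
    ``(0.0, 1.0)``.
    """
    counts = np.array([n_hom_risk, n_het, n_hom_other], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be >= 0")
    n = counts.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_hom_risk + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def odds_ratio_ci(a: float, b: float, c: float, d: float) -> tuple[float, float, float]:
    """Odds ratio ``ad/bc`` with Woolf 95% CI.

    If any cell is zero, 0.5 is added to all four cells
    (Haldane–Anscombe) before computing both the OR and the CI.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be >= 0")
    if a + b == 0 or c + d == 0:
        raise ValueError("each arm of the 2x2 table must contain observations")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return or_, math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se)


def _test_2x2(a: int, b: int, c: int, d: int) -> tuple[float, str]:
    """Pearson chi-square p, or two-sided Fisher exact if any expected cell < 5."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected < 5).any():
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return float(p), "fisher"
    chi2_stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p), "chi2"


def _finish(a: int, b: int, c: int, d: int, marker_id: str, comparison: str, model: str) -> AssociationResult:
    # monomorphic in both arms: no contrast to test
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        return AssociationResult(
            marker_id, comparison, model, a, b, c, d,
            p_value=1.0, odds_ratio=1.0, ci_low=1.0, ci_high=1.0,
            test_used="none", untestable=True,
        )
    p, test_used = _test_2x2(a, b, c, d)
    or_, lo, hi = odds_ratio_ci(a, b, c, d)
    return AssociationResult(
        marker_id, comparison, model, a, b, c, d,
        p_value=p, odds_ratio=or_, ci_low=lo, ci_high=hi, test_used=test_used,
    )


def _clean(dosages: np.ndarray) -> np.ndarray:
    dosages = np.asarray(dosages, dtype=float)
    return dosages[~np.isnan(dosages)]


def allelic_test(
    case_dosages: np.ndarray,
    ref_dosages: np.ndarray,
    marker_id: str = "marker",
    comparison: str = "CD_vs_ctrl",
) -> AssociationResult:
    """Risk-allele vs other-allele 2x2 test (2 chromosomes per subject)."""
    case = _clean(case_dosages)
    ref = _clean(ref_dosages)
    if case.size == 0 or ref.size == 0:
        raise ValueError("each arm needs at least one non-missing dosage")
    a = int(case.sum())
    b = int(2 * case.size - a)
    c = int(ref.sum())
    d = int(2 * ref.size - c)
    return _finish(a, b, c, d, marker_id, comparison, "allelic")


def carrier_test(
    case_dosages: np.ndarray,
    ref_dosages: np.ndarray,
    marker_id: str = "marker",
    comparison: str = "CD_vs_ctrl",
) -> AssociationResult:
    """Carrier (dosage >= 1) vs non-carrier 2x2 test (dominant model)."""
    case = _clean(case_dosages)
    ref = _clean(ref_dosages)
    if case.size == 0 or ref.size == 0:
        raise ValueError("each arm needs at least one non-missing dosage")
    a = int((case >= 1).sum())
    b = int(case.size - a)
    c = int((ref >= 1).sum())
    d = int(ref.size - c)
    return _finish(a, b, c, d, marker_id, comparison, "carrier")


def composite_indicator(
    cohort: Cohort,
    member_snp_ids: tuple[str, ...] = NOD2_SNPS,
    missing_policy: str = "optimistic",
) -> np.ndarray:
    """Per-subject carrier indicator over a set of member SNPs.

    1 if any member dosage >= 1; 0 if every observed member is 0; NaN if
    all members are missing.  Under the default ``optimistic`` policy a
    partially-missing subject with no observed risk genotype counts as 0;
    ``strict`` marks such subjects missing instead.
    """
    if not member_snp_ids:
        raise ValueError("member_snp_ids must be non-empty")
    if missing_policy not in ("optimistic", "strict"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    cols = np.column_stack([cohort.dosages_for(s) for s in member_snp_ids])
    any_risk = np.nansum(cols >= 1, axis=1) > 0
    n_obs = (~np.isnan(cols)).sum(axis=1)
    out = np.where(any_risk, 1.0, 0.0)
    out[n_obs == 0] = np.nan
    if missing_policy == "strict":
        out[(n_obs < len(member_snp_ids)) & ~any_risk] = np.nan
    return out


def bonferroni_threshold(alpha: float = 0.05, n_loci: int = 19) -> float:
    """Family-wise threshold alpha / n_loci."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    return alpha / n_loci


@dataclass
class AssociationTable:
    """All marker x comparison x model results for one cohort."""

    results: list[AssociationResult] = field(default_factory=list)
    alpha: float = 0.05
    n_loci: int = 19

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.results])
        if not df.empty:
            # opposite-allele orientation, for table-faithful output
            df["odds_ratio_flipped"] = 1.0 / df["odds_ratio"]
            df["ci_low_flipped"] = 1.0 / df["ci_high"]
            df["ci_high_flipped"] = 1.0 / df["ci_low"]
        return df


def run_comparisons(
    cohort: Cohort,
    models: tuple[str, ...] = ("allelic", "carrier"),
    composites: tuple[CompositeMarker, ...] = (),
    comparisons: tuple[str, ...] = tuple(COMPARISONS),
    alpha: float = 0.05,
    n_loci: int | None = None,
) -> AssociationTable:
    """Run every requested marker x comparison x model test.

    Comparisons whose site groups are absent from the cohort are skipped
    with a warning.  Markers monomorphic in both arms come back flagged
    untestable with p = 1.
    """
    for m in models:
        if m not in ("allelic", "carrier"):
            raise ValueError(f"unknown model {m!r}")
    if n_loci is None:
        n_loci = cohort.panel.n_loci
    thresh = bonferroni_threshold(alpha, n_loci)
    sites_present = cohort.present_sites()
    has_controls = bool(cohort.group_mask("control").sum())
    table = AssociationTable(alpha=alpha, n_loci=n_loci)

    markers: list[tuple[str, np.ndarray, tuple[str, ...], bool]] = [
        (e.snp_id, cohort.dosages_for(e.snp_id), models, False) for e in cohort.panel
    ]
    for comp_marker in composites:
        ind = composite_indicator(cohort, comp_marker.member_snp_ids)
        # a composite is already an indicator: only the carrier model applies
        markers.append((comp_marker.marker_id, ind, ("carrier",), True))

    n_fisher = 0
    for label in comparisons:
        comp = Comparison.from_label(label)
        needed_sites = {g for g in (comp.case_group, comp.reference_group) if g in ("L1", "L2", "L3")}
        if needed_sites - sites_present or (
            "control" in (comp.case_group, comp.reference_group) and not has_controls
        ):
            logger.warning("comparison %s skipped: group(s) absent from cohort", label)
            continue
        case_mask = cohort.group_mask(comp.case_group)
        ref_mask = cohort.group_mask(comp.reference_group)
        for marker_id, dosages, marker_models, is_composite in markers:
            for model in marker_models:
                test = allelic_test if model == "allelic" else carrier_test
                res = test(dosages[case_mask], dosages[ref_mask], marker_id, label)
                res.composite = is_composite
                res.nominal_significant = (not res.untestable) and res.p_value < alpha
                res.bonferroni_significant = (not res.untestable) and res.p_value < thresh
                if res.test_used == "fisher":
                    n_fisher += 1
                table.results.append(res)
    logger.info(
        "association battery: %d tests, %d Fisher fallbacks", len(table.results), n_fisher
    )
    return table


def tally_significant(
    table: AssociationTable | PrintedTableFixture | pd.DataFrame,
    comparison: str,
    alpha: float = 0.05,
    include_composite: bool = False,
    model: str | None = None,
) -> int:
    """Number of markers with p < alpha in one comparison.

    Accepts a computed :class:`AssociationTable` (``model`` selects which
    genetic model to count; defaults to carrier when present) or a
    printed-table fixture.  Composite rows are counted only when
    ``include_composite`` is set.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    if isinstance(table, PrintedTableFixture):
        if table.table_id == "table2":
            if comparison != "CD_vs_ctrl":
                raise ValueError("table2 fixture only covers CD_vs_ctrl")
            df = table.rows
            if not include_composite:
                df = df[~df["composite_flag"]]
            return int((df["p_value"] < alpha).sum())
        if table.table_id == "table3":
            cells = table.cells
            sub = cells[cells["comparison"] == comparison]
            if not include_composite:
                sub = sub[~sub["composite_flag"]]
            return int((sub["p_value"] < alpha).sum())
        raise ValueError("table1 fixture carries no p-values")
    df = table.to_frame() if isinstance(table, AssociationTable) else table
    if df.empty:
        return 0
    sub = df[df["comparison"] == comparison]
    if model is not None:
        sub = sub[sub["model"] == model]
    if not include_composite:
        sub = sub[~sub["composite"]]
    return int(((sub["p_value"] < alpha) & ~sub["untestable"]).sum())
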
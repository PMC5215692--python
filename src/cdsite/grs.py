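"""Genetic risk score construction and ROC/AUC evaluation.

A subject's weighted GRS is the sum over markers of risk-allele dosage
times the marker's log odds ratio; the allele-count GRS uses unit
weights (a plain count of risk alleles).  Weights come from an
association table, and every weight is made non-negative by *orienting*
the marker: a protective marker (OR < 1) has its allele flipped (dosage
2 - d) and its OR inverted, so it contributes positively through its
protective allele.  Discrimination between cases and controls is read
off the ROC curve; the AUC is computed through the Mann–Whitney U
identity (ties counted one-half) and cross-checked against trapezoidal
integration of the curve itself.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationTable
from .cohort import Cohort

logger = logging.getLogger(__name__)


@dataclass
class GrsEntry:
    marker_id: str
    orientation: str  # "as-panel" | "flipped"
    weight: float  # log-odds units (1.0 in allele-count mode)


@dataclass
class GrsModel:
    """Oriented per-marker weights plus the scoring mode."""

    entries: list[GrsEntry] = field(default_factory=list)
    mode: str = "weighted"  # "weighted" | "allele_count"
    source_comparison: str = "CD_vs_ctrl"

    @property
    def marker_ids(self) -> list[str]:
        return [e.marker_id for e in self.entries]


@dataclass
class RocCurve:
    """Threshold sweep with AUC and its normal-approximation p-value."""

    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_p_value: float
    n_cases: int
    n_controls: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def build_weights(
    assoc: AssociationTable | pd.DataFrame,
    marker_ids: list[str],
    mode: str = "weighted",
    comparison: str = "CD_vs_ctrl",
    model: str = "allelic",
    drop_protective: bool = False,
) -> GrsModel:
    """Turn association ORs into an oriented GRS model.

    Weight = ln(OR); markers with OR < 1 are flipped (allele swapped, OR
    inverted) so all weights are non-negative — the "positive scores"
    construction.  Setting ``drop_protective`` instead discards OR < 1
    markers.  In ``allele_count`` mode all weights are 1 with the same
    orientation.  Untestable markers or OR <= 0 are excluded with a
    warning.
    """
    if mode not in ("weighted", "allele_count"):
        raise ValueError(f"unknown mode {mode!r}")
    df = assoc.to_frame() if isinstance(assoc, AssociationTable) else assoc
    sub = df[(df["comparison"] == comparison) & (df["model"] == model)]
    # composites only exist under the carrier model
    missing_model = [m for m in marker_ids if m not in set(sub["marker_id"])]
    if missing_model:
        extra = df[(df["comparison"] == comparison) & df["marker_id"].isin(missing_model)]
        sub = pd.concat([sub, extra])
    by_id = sub.set_index("marker_id")
    entries: list[GrsEntry] = []
    for mid in marker_ids:
        if mid not in by_id.index:
            raise ValueError(f"marker {mid!r} has no result for {comparison}")
        row = by_id.loc[mid]
        or_ = float(row["odds_ratio"])
        if bool(row["untestable"]) or or_ <= 0 or not math.isfinite(or_):
            logger.warning("marker %s excluded from GRS (untestable or OR <= 0)", mid)
            continue
        if or_ < 1.0:
            if drop_protective:
                continue
            orientation, w = "flipped", math.log(1.0 / or_)
        else:
            orientation, w = "as-panel", math.log(or_)
        entries.append(GrsEntry(mid, orientation, 1.0 if mode == "allele_count" else w))
    return GrsModel(entries=entries, mode=mode, source_comparison=comparison)


def score_subjects(
    cohort: Cohort,
    model: GrsModel,
    extra_markers: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-subject GRS = sum of oriented dosage x weight.

    ``extra_markers`` supplies dosage vectors for markers outside the
    panel (e.g. a composite indicator).  A missing dosage contributes the
    marker's cohort-mean oriented dosage (logged); a subject missing
    every marker gets a NaN score.
    """
    extra_markers = extra_markers or {}
    scores = np.zeros(cohort.n_subjects)
    n_obs = np.zeros(cohort.n_subjects, dtype=int)
    for entry in model.entries:
        if entry.marker_id in cohort.panel:
            d = cohort.dosages_for(entry.marker_id).astype(float).copy()
            max_dose = 2.0
        elif entry.marker_id in extra_markers:
            d = np.asarray(extra_markers[entry.marker_id], dtype=float).copy()
            max_dose = float(np.nanmax(d)) if np.isfinite(np.nanmax(d)) else 1.0
        else:
            raise ValueError(f"marker {entry.marker_id!r} not in panel or extras")
        if entry.orientation == "flipped":
            d = max_dose - d
        miss = np.isnan(d)
        if miss.all():
            raise ValueError(f"marker {entry.marker_id!r} has no observed dosages")
        if miss.any():
            mean_d = float(np.nanmean(d))
            logger.info(
                "%s: imputing %d missing dosages with cohort mean %.3f",
                entry.marker_id, int(miss.sum()), mean_d,
            )
            d[miss] = mean_d
        scores += d * entry.weight
        n_obs += 1
    scores[n_obs == 0] = np.nan
    return scores


def _mann_whitney_auc(case_scores: np.ndarray, control_scores: np.ndarray) -> tuple[float, float]:
    """AUC = U / (n1*n2) with ties one-half, and tie-corrected normal p."""
    res = stats.mannwhitneyu(
        case_scores, control_scores, alternative="two-sided", method="asymptotic"
    )
    auc = float(res.statistic) / (len(case_scores) * len(control_scores))
    return auc, float(res.pvalue)


def roc_auc(case_scores: np.ndarray, control_scores: np.ndarray) -> RocCurve:
    """ROC threshold sweep over the pooled unique scores.

    A subject is called positive when score >= threshold.  The AUC comes
    from the Mann–Whitney identity; the trapezoidal integral of the swept
    curve is asserted to agree (they are equal identities, so any gap is
    an implementation bug).  The p-value tests AUC = 0.5 via the normal
    approximation to U with tie correction.
    """
    case = np.asarray(case_scores, dtype=float)
    ctrl = np.asarray(control_scores, dtype=float)
    case = case[~np.isnan(case)]
    ctrl = ctrl[~np.isnan(ctrl)]
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("each arm needs at least one non-missing score")
    pooled = np.concatenate([case, ctrl])
    uniq = np.unique(pooled)[::-1]
    # +inf / -inf bracket the sweep so the curve runs (0,0) -> (1,1)
    thresholds = np.concatenate([[np.inf], uniq, [-np.inf]])
    sens = np.array([(case >= t).mean() for t in thresholds])
    spec = np.array([(ctrl < t).mean() for t in thresholds])
    if np.ptp(pooled) == 0:
        auc_u, p = 0.5, 1.0  # a constant score carries no signal
    else:
        auc_u, p = _mann_whitney_auc(case, ctrl)
    fpr = 1.0 - spec
    auc_trapz = float(np.trapezoid(sens, fpr))
    assert abs(auc_trapz - auc_u) < 1e-9, (auc_trapz, auc_u)
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc_u,
        auc_p_value=p,
        n_cases=case.size,
        n_controls=ctrl.size,
    )


def auc_p_exact(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """Exact permutation p-value for AUC != 0.5 (small arms only).

    Enumerates every split of the pooled scores into arms of the observed
    sizes; feasible for n <= 30 pooled observations.
    """
    pooled = np.concatenate([case_scores, control_scores])
    n1 = len(case_scores)
    if len(pooled) > 30:
        raise ValueError("exact permutation limited to 30 pooled scores")
    observed = abs(_mann_whitney_auc(case_scores, control_scores)[0] - 0.5)
    count = 0
    total = 0
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        auc = _mann_whitney_auc(pooled[mask], pooled[~mask])[0]
        if abs(auc - 0.5) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def optimal_cutoff(roc: RocCurve, method: str = "youden") -> tuple[float, float, float]:
    """Operating cutoff maximizing Youden's J = sensitivity + specificity - 1.

    The reported cutoff is the midpoint between the optimal threshold
    score and the next lower distinct score, so a "5.5" style cutoff
    falls between attainable integer allele counts.  At a tied optimum
    the sweep keeps the first (highest-threshold, most specific)
    operating point — a deterministic tie-break.
    """
    if method != "youden":
        raise ValueError(f"unknown cutoff method {method!r}")
    j = roc.sensitivity + roc.specificity - 1.0
    # skip the leading +inf (predict-nobody) corner; descending sweep
    best = 1
    for i in range(2, len(roc.thresholds)):
        if j[i] > j[best] + 1e-12:
            best = i
    t = roc.thresholds[best]
    lower = roc.thresholds[best + 1] if best + 1 < len(roc.thresholds) else -np.inf
    cutoff = t if not np.isfinite(lower) else (t + lower) / 2.0
    return float(cutoff), float(roc.sensitivity[best]), float(roc.specificity[best])
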
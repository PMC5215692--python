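"""End-to-end pipeline: simulate/load -> associate -> stepwise -> GRS -> report.

A run is driven by one :class:`RunConfig` (usually read from YAML) and
produces a *bundle* directory: per-comparison association TSVs, a
significance-tally TSV, stepwise path/model TSVs, GRS ROC and summary
TSVs, and a ``manifest.json`` echoing the config and seed.  The same
config and seed always produce a byte-identical bundle; nothing
time-dependent is written.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    COMPARISONS,
    NOD2_SNPS,
    AssociationTable,
    CompositeMarker,
    bonferroni_threshold,
    composite_indicator,
    run_comparisons,
    tally_significant,
)
from .cohort import Cohort, load_cohort
from .grs import build_weights, optimal_cutoff, roc_auc, score_subjects
from .panel import load_packaged_panel, load_panel
from .simulate import load_sim_config, simulate_cohort
from .stepwise import forward_stepwise, interaction_screen


class StageError(RuntimeError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: Path
    panel_path: Path | None = None
    genotype_path: Path | None = None
    phenotype_path: Path | None = None
    sim_config_path: Path | None = None
    comparisons: tuple[str, ...] = tuple(COMPARISONS)
    alpha: float = 0.05
    n_loci: int | None = None
    p_enter: float = 0.05
    p_remove: float = 0.10
    grs_mode: str = "both"  # weighted | allele_count | both
    seed: int = 0
    run_stepwise: bool = True
    run_grs: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "comparisons" in raw:
            raw["comparisons"] = tuple(raw["comparisons"])
        for key in ("out_dir", "panel_path", "genotype_path", "phenotype_path", "sim_config_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.sim_config_path is None and (
            self.genotype_path is None or self.phenotype_path is None
        ):
            raise StageError("config", "need either sim_config_path or genotype+phenotype paths")
        for key in ("panel_path", "genotype_path", "phenotype_path", "sim_config_path"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise StageError("config", f"{key} does not exist: {p}")
        bad = [c for c in self.comparisons if c not in COMPARISONS]
        if bad:
            raise StageError("config", f"unknown comparison(s): {bad}")
        if self.grs_mode not in ("weighted", "allele_count", "both"):
            raise StageError("config", f"unknown grs_mode {self.grs_mode!r}")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _stage_cohort(config: RunConfig) -> Cohort:
    panel = load_panel(config.panel_path) if config.panel_path else load_packaged_panel()
    if config.sim_config_path is not None:
        sim = load_sim_config(config.sim_config_path)
        sim.seed = config.seed
        cohort, truth = simulate_cohort(sim, panel)
        truth.to_yaml(config.out_dir / "truth.yaml")
        return cohort
    return load_cohort(config.genotype_path, config.phenotype_path, panel)


def _stage_associate(config: RunConfig, cohort: Cohort) -> AssociationTable:
    composites = ()
    if all(s in cohort.panel for s in NOD2_SNPS):
        composites = (CompositeMarker("NOD2_any", NOD2_SNPS),)
    table = run_comparisons(
        cohort,
        composites=composites,
        comparisons=config.comparisons,
        alpha=config.alpha,
        n_loci=config.n_loci,
    )
    df = table.to_frame()
    for comp in sorted(set(df["comparison"])) if not df.empty else []:
        _write_tsv(df[df["comparison"] == comp], config.out_dir / f"association_{comp}.tsv")
    # tallies are bundle data so the report never recomputes anything
    tally_rows = []
    for comp in config.comparisons:
        if df.empty or comp not in set(df["comparison"]):
            continue
        for model in ("allelic", "carrier"):
            for include_composite in (False, True):
                tally_rows.append(
                    {
                        "comparison": comp,
                        "model": model,
                        "include_composite": include_composite,
                        "alpha": config.alpha,
                        "n_significant": tally_significant(
                            df, comp, config.alpha, include_composite, model=model
                        ),
                        "n_bonferroni": int(
                            (
                                df[(df["comparison"] == comp) & (df["model"] == model)]
                                .loc[lambda s: include_composite | ~s["composite"]]
                                ["bonferroni_significant"]
                            ).sum()
                        ),
                    }
                )
    _write_tsv(pd.DataFrame(tally_rows), config.out_dir / "tallies.tsv")
    return table


def _stepwise_candidates(
    cohort: Cohort, df: pd.DataFrame, comparison: str, threshold: float
) -> pd.DataFrame:
    """Carrier-coded design of Bonferroni-significant markers.

    The composite NOD2 indicator replaces its member SNPs whenever it is
    itself significant.
    """
    sub = df[(df["comparison"] == comparison) & (df["model"] == "carrier")]
    sig = sub[(sub["p_value"] < threshold) & ~sub["untestable"]]
    cols: dict[str, np.ndarray] = {}
    composite_in = any(sig["composite"])
    for mid, is_comp in zip(sig["marker_id"], sig["composite"]):
        if is_comp:
            cols[mid] = composite_indicator(cohort, NOD2_SNPS)
        elif composite_in and mid in NOD2_SNPS:
            continue  # replaced by the composite
        else:
            d = cohort.dosages_for(mid)
            cols[mid] = (d >= 1).astype(float)
            cols[mid][np.isnan(d)] = np.nan
    return pd.DataFrame(cols)


def _stage_stepwise(config: RunConfig, cohort: Cohort, table: AssociationTable) -> None:
    df = table.to_frame()
    threshold = bonferroni_threshold(config.alpha, table.n_loci)
    for comp in config.comparisons:
        if df.empty or comp not in set(df["comparison"]):
            continue
        case_sel, ref_sel = COMPARISONS[comp]
        case_mask = cohort.group_mask(case_sel)
        ref_mask = cohort.group_mask(ref_sel)
        use = case_mask | ref_mask
        outcome = case_mask[use].astype(float)
        candidates = _stepwise_candidates(cohort, df, comp, threshold)
        if candidates.empty:
            _write_tsv(
                pd.DataFrame(columns=["step", "action", "term", "lrt_p"]),
                config.out_dir / f"stepwise_path_{comp}.tsv",
            )
            continue
        candidates = candidates.loc[use].reset_index(drop=True)
        path = forward_stepwise(candidates, outcome, config.p_enter, config.p_remove)
        _write_tsv(path.to_frame(), config.out_dir / f"stepwise_path_{comp}.tsv")
        if path.final_fit is not None:
            _write_tsv(
                path.final_fit.odds_ratios(), config.out_dir / f"stepwise_model_{comp}.tsv"
            )
            if len(path.final_terms) >= 2:
                inter = interaction_screen(
                    candidates[list(path.final_terms)], outcome, config.alpha
                )
                _write_tsv(inter, config.out_dir / f"interactions_{comp}.tsv")


def _stage_grs(config: RunConfig, cohort: Cohort, table: AssociationTable) -> None:
    df = table.to_frame()
    if df.empty or "CD_vs_ctrl" not in set(df["comparison"]):
        raise StageError("grs", "GRS weights need the CD_vs_ctrl comparison")
    sig = df[
        (df["comparison"] == "CD_vs_ctrl")
        & (df["model"] == "allelic")
        & df["nominal_significant"]
        & ~df["composite"]
    ]
    marker_ids = list(sig["marker_id"])
    if not marker_ids:
        raise StageError("grs", "no nominally significant markers to score")
    modes = (
        ("weighted", "allele_count") if config.grs_mode == "both" else (config.grs_mode,)
    )
    summary_rows = []
    for mode in modes:
        model = build_weights(df, marker_ids, mode=mode)
        scores = score_subjects(cohort, model)
        for comp in config.comparisons:
            case_sel, ref_sel = COMPARISONS[comp]
            case_mask = cohort.group_mask(case_sel)
            ref_mask = cohort.group_mask(ref_sel)
            if not case_mask.any() or not ref_mask.any():
                continue
            roc = roc_auc(scores[case_mask], scores[ref_mask])
            cutoff, sens, spec = optimal_cutoff(roc)
            _write_tsv(roc.to_frame(), config.out_dir / f"roc_{mode}_{comp}.tsv")
            summary_rows.append(
                {
                    "mode": mode,
                    "comparison": comp,
                    "n_markers": len(model.entries),
                    "auc": roc.auc,
                    "auc_p_value": roc.auc_p_value,
                    "cutoff": cutoff,
                    "sensitivity": sens,
                    "specificity": spec,
                }
            )
    _write_tsv(pd.DataFrame(summary_rows), config.out_dir / "grs_summary.tsv")


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the bundle directory.

    On a stage failure the manifest is still written, with the failed
    stage recorded under ``incomplete``, then :class:`StageError`
    propagates.
    """
    config.validate()
    config.out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "cdsite",
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "stages": [],
        "incomplete": None,
    }
    stage = "cohort"
    try:
        cohort = _stage_cohort(config)
        manifest["n_subjects"] = cohort.n_subjects
        manifest["n_snps"] = len(cohort.panel)
        manifest["stages"].append("cohort")
        stage = "associate"
        table = _stage_associate(config, cohort)
        manifest["stages"].append("associate")
        if config.run_stepwise:
            stage = "stepwise"
            _stage_stepwise(config, cohort, table)
            manifest["stages"].append("stepwise")
        if config.run_grs:
            stage = "grs"
            _stage_grs(config, cohort, table)
            manifest["stages"].append("grs")
    except StageError:
        manifest["incomplete"] = stage
        _write_manifest(manifest, config.out_dir)
        raise
    except Exception as err:
        manifest["incomplete"] = stage
        _write_manifest(manifest, config.out_dir)
        raise StageError(stage, str(err)) from err
    _write_manifest(manifest, config.out_dir)
    return config.out_dir


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def render_report(bundle_dir: str | Path) -> str:
    """Human-readable summary of a bundle.

    Every number is read from a bundle file; nothing is recomputed here.
    Missing stages are reported as explicit gaps.
    """
    bundle_dir = Path(bundle_dir)
    lines = ["cdsite run report", "================="]
    manifest_path = bundle_dir / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        lines.append(f"seed: {manifest['seed']}   version: {manifest['version']}")
        if manifest.get("incomplete"):
            lines.append(f"WARNING: run incomplete, failed stage: {manifest['incomplete']}")
    else:
        lines.append("WARNING: no manifest found")

    tally_path = bundle_dir / "tallies.tsv"
    if tally_path.exists():
        tallies = pd.read_csv(tally_path, sep="\t")
        lines.append("")
        lines.append("significant markers per comparison (carrier model, composite included):")
        sub = tallies[
            (tallies["model"] == "carrier") & tallies["include_composite"]
        ]
        for _, row in sub.iterrows():
            lines.append(
                f"  {row['comparison']:<12} p<{row['alpha']}: {row['n_significant']:>3}"
                f"   Bonferroni: {row['n_bonferroni']:>3}"
            )
    else:
        lines.append("association tallies: MISSING")

    grs_path = bundle_dir / "grs_summary.tsv"
    lines.append("")
    if grs_path.exists():
        grs = pd.read_csv(grs_path, sep="\t")
        lines.append("GRS discrimination (AUC):")
        for _, row in grs.iterrows():
            lines.append(
                f"  {row['mode']:<12} {row['comparison']:<12} AUC={row['auc']:.3f} "
                f"p={row['auc_p_value']:.2e} cutoff={row['cutoff']:.2f} "
                f"sens={row['sensitivity']:.2f} spec={row['specificity']:.2f}"
            )
    else:
        lines.append("GRS stage: skipped")
    return "\n".join(lines) + "\n"
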
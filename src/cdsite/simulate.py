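"""Synthetic case-control cohort generator.

Because the real patient genotypes live in an anonymized clinical
database and were never deposited, analyses are exercised on simulated
cohorts that reproduce the statistical structure the methods assume:

* fixed group sizes (537 controls and 708 CD cases split 237 ileal /
  171 colonic / 300 ileocolonic by default — the study's design);
* per-SNP, per-group risk-allele frequencies (defaulting to the
  published case/control frequencies, with the all-CD frequency applied
  to every site unless overridden);
* Hardy–Weinberg genotype proportions within each group;
* optional pairwise linkage disequilibrium between SNPs sharing a locus
  block, parameterised by the haplotype correlation r;
* per-SNP missing-call dropout.

Disease-site labels are assigned by the fixed group sizes (case-control
sampling), not by a liability model, and covariates are independent of
genotype.  Each (group, SNP-or-pair) draw has its own PRNG stream spawned
from the master seed, so edits to one part of a config do not perturb the
rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import Cohort, SubjectRecord, write_cohort
from .fixtures import load_printed_table
from .panel import SnpPanel, load_packaged_panel

GROUP_ORDER = ("control", "L1", "L2", "L3")

DEFAULT_GROUP_SIZES = {"control": 537, "L1": 237, "L2": 171, "L3": 300}


class LdError(ValueError):
    """Requested LD is infeasible for the given allele frequencies."""


@dataclass
class SimConfig:
    """Everything needed to regenerate a synthetic cohort bit-identically."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    #: snp_id -> {group -> risk-allele frequency}; groups are GROUP_ORDER
    rafs: dict[str, dict[str, float]] = field(default_factory=dict)
    #: (snp_a, snp_b, target_r) pairs; both SNPs must share a locus_id
    ld_spec: list[tuple[str, str, float]] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self, panel: SnpPanel) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUP_ORDER:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError(f"group size for {g} must be >= 0")
        for snp, freqs in self.rafs.items():
            if snp not in panel:
                raise ValueError(f"RAF given for {snp!r}, which is not in the panel")
            for g, p in freqs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{snp}/{g}: RAF {p} outside [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        for snp_a, snp_b, r in self.ld_spec:
            if abs(r) > 1:
                raise ValueError(f"LD pair ({snp_a}, {snp_b}): |r| must be <= 1")
            if panel[snp_a].locus_id != panel[snp_b].locus_id:
                raise ValueError(
                    f"LD pair ({snp_a}, {snp_b}) spans two loci "
                    f"({panel[snp_a].locus_id}, {panel[snp_b].locus_id})"
                )


@dataclass
class SimTruth:
    """Ground truth of one simulation run, sufficient to audit recovery."""

    seed: int
    group_sizes: dict[str, int]
    generating_rafs: dict[str, dict[str, float]]
    #: allelic odds ratio implied by each SNP's (case-site, control) RAF pair
    generating_ors: dict[str, dict[str, float]]
    realized_rafs: dict[str, dict[str, float]]
    ld_pairs: list[dict]
    missing_rate: float

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(vars(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def hwe_genotype_probs(p: float) -> tuple[float, float, float]:
    """Hardy–Weinberg genotype probabilities (P(2), P(1), P(0)) at frequency p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    q = 1.0 - p
    return (p * p, 2 * p * q, q * q)


def ld_feasible_r(p_a: float, p_b: float) -> tuple[float, float]:
    """Feasible interval of the haplotype correlation r for two frequencies."""
    qa, qb = 1 - p_a, 1 - p_b
    denom = math.sqrt(p_a * qa * p_b * qb)
    if denom == 0:
        return (0.0, 0.0)
    d_min = -min(p_a * p_b, qa * qb)
    d_max = min(p_a * qb, qa * p_b)
    return (d_min / denom, d_max / denom)


def pair_haplotype_freqs(
    p_a: float, p_b: float, target_r: float
) -> tuple[float, float, float, float]:
    """Two-locus haplotype frequencies (AB, Ab, aB, ab) at correlation r.

    ``A``/``B`` denote the risk alleles.  D = r * sqrt(pa*qa*pb*qb) is
    added to the independence products; an infeasible r raises
    :class:`LdError` reporting the feasible interval.
    """
    for p in (p_a, p_b):
        if not 0.0 <= p <= 1.0:
            raise ValueError("allele frequencies must be in [0, 1]")
    qa, qb = 1 - p_a, 1 - p_b
    d = target_r * math.sqrt(p_a * qa * p_b * qb)
    r_lo, r_hi = ld_feasible_r(p_a, p_b)
    if not (r_lo - 1e-12 <= target_r <= r_hi + 1e-12):
        raise LdError(
            f"r = {target_r} infeasible for frequencies ({p_a}, {p_b}); "
            f"feasible interval is [{r_lo:.4f}, {r_hi:.4f}]"
        )
    freqs = (p_a * p_b + d, p_a * qb - d, qa * p_b - d, qa * qb + d)
    return tuple(max(0.0, f) for f in freqs)  # clip FP dust at the boundary


def default_sim_config(seed: int = 0, missing_rate: float = 0.0) -> SimConfig:
    """Study-condition defaults: published group sizes and case/control RAFs.

    The published per-site allele frequencies were never printed, so the
    all-CD case frequency is applied to every site; site-contrast
    experiments must override per-site frequencies explicitly.
    """
    t2 = load_printed_table("table2").rows
    rafs: dict[str, dict[str, float]] = {}
    for _, row in t2.iterrows():
        rafs[row["snp_id"]] = {
            "control": float(row["raf_control"]),
            "L1": float(row["raf_case"]),
            "L2": float(row["raf_case"]),
            "L3": float(row["raf_case"]),
        }
    return SimConfig(rafs=rafs, seed=seed, missing_rate=missing_rate)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _group_raf(config: SimConfig, snp_id: str, group: str) -> float:
    freqs = config.rafs.get(snp_id, {})
    if group in freqs:
        return freqs[group]
    raise ValueError(f"no RAF configured for {snp_id} in group {group}")


def simulate_cohort(config: SimConfig, panel: SnpPanel | None = None) -> tuple[Cohort, SimTruth]:
    """Draw one cohort under the configured generating model.

    SNPs not in an LD pair are drawn independently from Hardy–Weinberg
    proportions; each LD pair is drawn as two haplotypes per subject from
    its four-haplotype distribution.  Dropout is applied last.  The same
    config and seed always give an identical cohort.
    """
    if panel is None:
        panel = load_packaged_panel()
    config.validate(panel)

    # fail on infeasible LD before anything is generated
    paired: dict[str, int] = {}
    for k, (sa, sb, r) in enumerate(config.ld_spec):
        if sa in paired or sb in paired:
            raise ValueError(f"SNP in more than one LD pair: ({sa}, {sb})")
        for g in GROUP_ORDER:
            if config.group_sizes.get(g, 0) > 0:
                pair_haplotype_freqs(_group_raf(config, sa, g), _group_raf(config, sb, g), r)
        paired[sa] = k
        paired[sb] = k

    subjects: list[SubjectRecord] = []
    group_slices: dict[str, slice] = {}
    start = 0
    for g in GROUP_ORDER:
        n = config.group_sizes.get(g, 0)
        for i in range(n):
            sid = f"{'C' if g == 'control' else g}{i + 1:05d}"
            if g == "control":
                subjects.append(SubjectRecord(sid, "control", "none"))
            else:
                subjects.append(SubjectRecord(sid, "CD", g))
        group_slices[g] = slice(start, start + n)
        start += n

    n_total = start
    dosage = np.full((n_total, len(panel)), np.nan)
    realized: dict[str, dict[str, float]] = {e.snp_id: {} for e in panel}
    ld_out: list[dict] = []

    for gi, g in enumerate(GROUP_ORDER):
        n = config.group_sizes.get(g, 0)
        if n == 0:
            continue
        sl = group_slices[g]
        for j, entry in enumerate(panel):
            if entry.snp_id in paired:
                continue
            p = _group_raf(config, entry.snp_id, g)
            rng = _stream(config.seed, 0, gi, j)
            probs = hwe_genotype_probs(p)  # (P2, P1, P0)
            draws = rng.choice([2.0, 1.0, 0.0], size=n, p=probs)
            dosage[sl, j] = draws
            realized[entry.snp_id][g] = float(draws.sum() / (2 * n))
        for k, (sa, sb, r) in enumerate(config.ld_spec):
            pa = _group_raf(config, sa, g)
            pb = _group_raf(config, sb, g)
            hap = pair_haplotype_freqs(pa, pb, r)
            rng = _stream(config.seed, 1, gi, k)
            # two haplotypes per subject; haplotype 0=AB,1=Ab,2=aB,3=ab
            h = rng.choice(4, size=(n, 2), p=np.array(hap) / sum(hap))
            a_dose = np.isin(h, (0, 1)).sum(axis=1).astype(float)
            b_dose = np.isin(h, (0, 2)).sum(axis=1).astype(float)
            ja, jb = panel.index_of(sa), panel.index_of(sb)
            dosage[sl, ja] = a_dose
            dosage[sl, jb] = b_dose
            realized[sa][g] = float(a_dose.sum() / (2 * n))
            realized[sb][g] = float(b_dose.sum() / (2 * n))
            if a_dose.std() > 0 and b_dose.std() > 0:
                realized_r = float(np.corrcoef(a_dose, b_dose)[0, 1])
            else:
                realized_r = float("nan")
            ld_out.append(
                {"snp_a": sa, "snp_b": sb, "group": g, "target_r": float(r),
                 "realized_dosage_r": realized_r}
            )

    if config.missing_rate > 0:
        for gi, g in enumerate(GROUP_ORDER):
            n = config.group_sizes.get(g, 0)
            if n == 0:
                continue
            sl = group_slices[g]
            for j in range(len(panel)):
                rng = _stream(config.seed, 2, gi, j)
                drop = rng.random(n) < config.missing_rate
                block = dosage[sl, j]
                block[drop] = np.nan
                dosage[sl, j] = block

    gen_ors: dict[str, dict[str, float]] = {}
    for entry in panel:
        gen_ors[entry.snp_id] = {}
        p0 = config.rafs.get(entry.snp_id, {}).get("control")
        if p0 is None or p0 in (0.0, 1.0):
            continue
        for g in ("L1", "L2", "L3"):
            p1 = config.rafs.get(entry.snp_id, {}).get(g)
            if p1 is None or p1 in (0.0, 1.0):
                continue
            gen_ors[entry.snp_id][g] = (p1 / (1 - p1)) / (p0 / (1 - p0))

    truth = SimTruth(
        seed=config.seed,
        group_sizes={g: int(config.group_sizes.get(g, 0)) for g in GROUP_ORDER},
        generating_rafs={s: dict(f) for s, f in config.rafs.items()},
        generating_ors=gen_ors,
        realized_rafs=realized,
        ld_pairs=ld_out,
        missing_rate=float(config.missing_rate),
    )
    return Cohort(subjects, panel, dosage), truth


def simulate_to_files(
    config: SimConfig, out_dir: str | Path, panel: SnpPanel | None = None
) -> tuple[Path, Path, Path]:
    """Simulate and write genotypes.tsv, phenotypes.tsv and truth.yaml."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort, truth = simulate_cohort(config, panel)
    gpath = out_dir / "genotypes.tsv"
    ppath = out_dir / "phenotypes.tsv"
    tpath = out_dir / "truth.yaml"
    write_cohort(cohort, gpath, ppath)
    truth.to_yaml(tpath)
    return gpath, ppath, tpath


def load_sim_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from a YAML file (keys mirror the dataclass)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    ld = [tuple(x) for x in raw.get("ld_spec", [])]
    cfg = SimConfig(
        group_sizes=dict(raw.get("group_sizes", DEFAULT_GROUP_SIZES)),
        rafs={k: dict(v) for k, v in raw.get("rafs", {}).items()},
        ld_spec=ld,
        missing_rate=float(raw.get("missing_rate", 0.0)),
        seed=int(raw.get("seed", 0)),
    )
    if not cfg.rafs:
        cfg.rafs = default_sim_config().rafs
    return cfg
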
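"""SNP panel data model and reader.

A *panel* is the ordered list of SNPs a cohort was genotyped for.  Each
entry carries an explicit risk/other allele pair; all downstream dosage
coding (0/1/2 copies of the risk allele) is oriented by this panel, never
by which allele happens to be minor in a particular sample.

SNPs are grouped into loci via ``locus_id`` (a cytogenetic-band key such
as ``5q31``); the number of distinct loci is the denominator of the
Bonferroni correction used by the association module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

PANEL_COLUMNS = (
    "snp_id",
    "chrom_band",
    "locus_id",
    "gene_label",
    "risk_allele",
    "other_allele",
)


class PanelError(ValueError):
    """Malformed panel file (bad allele, duplicate SNP, missing column)."""


@dataclass(frozen=True)
class SnpPanelEntry:
    """One genotyped SNP with its risk-allele orientation."""

    snp_id: str
    chrom_band: str
    locus_id: str
    gene_label: str
    risk_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.risk_allele not in VALID_BASES:
            raise PanelError(
                f"{self.snp_id}: risk allele {self.risk_allele!r} is not one of A/C/G/T"
            )
        if self.other_allele not in VALID_BASES:
            raise PanelError(
                f"{self.snp_id}: other allele {self.other_allele!r} is not one of A/C/G/T"
            )
        if self.risk_allele == self.other_allele:
            raise PanelError(
                f"{self.snp_id}: risk and other allele are both {self.risk_allele!r}"
            )


class SnpPanel:
    """Ordered, uniquely-keyed collection of :class:`SnpPanelEntry`."""

    def __init__(self, entries: list[SnpPanelEntry]):
        seen: dict[str, int] = {}
        for i, e in enumerate(entries):
            if e.snp_id in seen:
                raise PanelError(f"duplicate snp_id {e.snp_id!r} in panel")
            seen[e.snp_id] = i
        self.entries: tuple[SnpPanelEntry, ...] = tuple(entries)
        self._index = seen

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SnpPanelEntry]:
        return iter(self.entries)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def __getitem__(self, snp_id: str) -> SnpPanelEntry:
        return self.entries[self._index[snp_id]]

    def index_of(self, snp_id: str) -> int:
        return self._index[snp_id]

    @property
    def snp_ids(self) -> list[str]:
        return [e.snp_id for e in self.entries]

    @property
    def locus_ids(self) -> list[str]:
        """Distinct locus keys, in panel order."""
        out: list[str] = []
        for e in self.entries:
            if e.locus_id not in out:
                out.append(e.locus_id)
        return out

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def snps_in_locus(self, locus_id: str) -> list[str]:
        return [e.snp_id for e in self.entries if e.locus_id == locus_id]


def load_panel(path: str | Path) -> SnpPanel:
    """Read a tab-separated panel file.

    Expected header: ``snp_id  chrom_band  locus_id  gene_label
    risk_allele  other_allele`` (extra columns ignored).  Raises
    :class:`PanelError` naming the offending line for malformed alleles,
    duplicate SNP ids or missing columns; an empty body yields an empty
    panel with a logged warning.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise PanelError(f"{path}: empty file, no header")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in PANEL_COLUMNS if c not in header]
    if missing:
        raise PanelError(f"{path}:1: missing column(s) {', '.join(missing)}")
    col = {c: header.index(c) for c in PANEL_COLUMNS}
    entries: list[SnpPanelEntry] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < len(header) - (len(header) - max(col.values()) - 1):
            raise PanelError(f"{path}:{lineno}: expected {len(header)} fields")
        try:
            entries.append(
                SnpPanelEntry(
                    snp_id=fields[col["snp_id"]].strip(),
                    chrom_band=fields[col["chrom_band"]].strip(),
                    locus_id=fields[col["locus_id"]].strip(),
                    gene_label=fields[col["gene_label"]].strip(),
                    risk_allele=fields[col["risk_allele"]].strip().upper(),
                    other_allele=fields[col["other_allele"]].strip().upper(),
                )
            )
        except PanelError as err:
            raise PanelError(f"{path}:{lineno}: {err}") from None
        except IndexError:
            raise PanelError(f"{path}:{lineno}: truncated row") from None
    if not entries:
        logger.warning("panel file %s has a valid header but no entries", path)
    return SnpPanel(entries)


def load_packaged_panel() -> SnpPanel:
    """The bundled 29-SNP / 19-locus Crohn's disease panel."""
    with resources.as_file(resources.files("cdsite.data") / "panel.tsv") as p:
        return load_panel(p)
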
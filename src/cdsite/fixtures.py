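"""Packaged fixtures of the published summary tables.

The source study's patient genotypes were never deposited, so its printed
summary tables travel with the package as data: the clinical-summary
table (``table1``), the case-control allelic results for all 29 SNPs
(``table2``) and the site-stratified carrier-genotype results for 19 SNPs
plus the composite NOD2 row (``table3``).  These are *fixture data* —
inputs for tally and summary operations — not recomputation targets:
several printed odds ratios are not reconstructible from the printed
allele frequencies under any standard 2x2 formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

TABLE_IDS = ("table1", "table2", "table3")

#: comparison labels used by table3 cells, in printed column order
TABLE3_COMPARISONS = (
    "L1_vs_ctrl",
    "L2_vs_ctrl",
    "L3_vs_ctrl",
    "L1_vs_L2",
    "L3_vs_L2",
    "L3_vs_L1",
)


@dataclass
class PrintedTableFixture:
    """One published table: ``rows`` is the wide layout, ``cells`` tidy."""

    table_id: str
    rows: pd.DataFrame
    cells: pd.DataFrame | None = None


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("cdsite.data") / name) as p:
        return pd.read_csv(p, sep="\t")


def load_printed_table(table_id: str) -> PrintedTableFixture:
    """Load a packaged printed-table fixture by id."""
    if table_id not in TABLE_IDS:
        raise ValueError(f"unknown table_id {table_id!r}; expected one of {TABLE_IDS}")
    if table_id == "table1":
        return PrintedTableFixture("table1", _read("table1.tsv"))
    if table_id == "table2":
        df = _read("table2.tsv")
        df["composite_flag"] = df["composite_flag"].astype(bool)
        df["bonferroni_flag"] = df["bonferroni_flag"].astype(bool)
        return PrintedTableFixture("table2", df)
    cells = _read("table3.tsv")
    cells["composite_flag"] = cells["composite_flag"].astype(bool)
    cells["bonferroni_flag"] = cells["bonferroni_flag"].astype(bool)
    # pivot to the printed 20-row x 6-comparison layout
    marker_order = list(dict.fromkeys(cells["marker_id"]))
    wide = pd.DataFrame(index=marker_order)
    meta = cells.drop_duplicates("marker_id").set_index("marker_id")
    wide["gene_label"] = meta["gene_label"]
    wide["composite_flag"] = meta["composite_flag"]
    for comp in TABLE3_COMPARISONS:
        sub = cells[cells["comparison"] == comp].set_index("marker_id")
        for col in ("p_value", "odds_ratio", "ci_low", "ci_high"):
            wide[f"{col}_{comp}"] = sub[col]
        wide[f"bonf_{comp}"] = sub["bonferroni_flag"]
    wide.index.name = "marker_id"
    return PrintedTableFixture("table3", wide.reset_index(), cells)
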
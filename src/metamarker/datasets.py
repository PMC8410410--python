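"""Packaged reference tables for the miR-1-3p / HNSCC case study.

Small plain-text fixtures shipped with the package: published per-arm
summary statistics (n, mean, SD) and Youden-cutoff confusion counts for
miR-1-3p expression across 18 public head-and-neck squamous cell
carcinoma (HNSCC) microarray datasets, the TCGA-HNSC miRNA-seq
clinical-parameter summary table, per-dataset country/year metadata, and
the five cancer-related KEGG pathway gene lists used for hub-gene
counting.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import StudyRecord, read_gmt, read_summary_table
from .summary import ArmSummary

__all__ = [
    "chip_summaries",
    "chip_info",
    "tcga_clinical_table",
    "tcga_tissue_record",
    "kegg_pathway_sets",
    "all_study_records",
]

_DATA = resources.files("metamarker") / "data"


def chip_summaries() -> list[StudyRecord]:
    """Arm summaries + 2×2 counts of the 18 microarray datasets."""
    with resources.as_file(_DATA / "hnsc_chip_summaries.tsv") as p:
        return read_summary_table(p)


def chip_info() -> pd.DataFrame:
    """Country and publication year per microarray dataset."""
    with resources.as_file(_DATA / "hnsc_chip_info.tsv") as p:
        return pd.read_csv(p, sep="\t")


def tcga_clinical_table() -> pd.DataFrame:
    """TCGA-HNSC clinical-parameter arm summaries (parameter, level, n, mean, sd)."""
    with resources.as_file(_DATA / "hnsc_tcga_clinical.tsv") as p:
        return pd.read_csv(p, sep="\t")


def tcga_tissue_record() -> StudyRecord:
    """The TCGA-HNSC tumor-vs-normal comparison as a StudyRecord."""
    df = tcga_clinical_table()
    tissue = df[df["parameter"] == "Tissue"].set_index("level")
    case = tissue.loc["HNSCC"]
    control = tissue.loc["Normal"]
    return StudyRecord(
        study_id="TCGA-HNSC",
        case=ArmSummary(int(case["n"]), float(case["mean"]), float(case["sd"])),
        control=ArmSummary(int(control["n"]), float(control["mean"]), float(control["sd"])),
        country="USA",
    )


def all_study_records() -> list[StudyRecord]:
    """The 19 datasets entering the expression meta-analysis: 18 chips + TCGA."""
    return chip_summaries() + [tcga_tissue_record()]


def kegg_pathway_sets() -> dict[str, set[str]]:
    """The five enriched KEGG pathway gene lists (hsa05200, 05205, 04151, 04510, 05206)."""
    with resources.as_file(_DATA / "hnsc_kegg_pathways.gmt") as p:
        return read_gmt(p)
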
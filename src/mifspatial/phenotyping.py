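"""Positivity calling, phenotype assignment, marker fractions and QC.

Lineage logic follows standard mIF practice for a melanoma panel:
SOX10 anchors the melanoma lineage, CD3 the T-cell lineage, CD31 the
endothelium.  Metabolic markers (GLUT1, GLUT3, CA9, HIF1a) are state
flags combinable on melanoma or T-cells (e.g. CD3+GLUT3+GLUT1-).

Intensity thresholding stands in for the pathologist's membranous-
staining criterion; the comparison is inclusive (``intensity >=
threshold`` is positive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_io import CellTable, PanelConfig, SampleMeta

logger = logging.getLogger(__name__)

PHENOTYPES = ("melanoma", "tcell", "endothelium", "other")


@dataclass
class QCReport:
    """Sample-level eligibility for the analysis tiers.

    ``eligible_spatial`` requires at least ``min_immune_cells`` immune
    and ``min_melanoma_cells`` melanoma cells.  Dedifferentiated samples
    are excluded from analyses relying on melanoma identification;
    samples whose GLUT1 signal came from erythrocytes alone are excluded
    from GLUT1-specific analyses.
    """

    sample_id: str
    n_melanoma: int
    n_immune: int
    eligible_spatial: bool
    eligible_tumor_analysis: bool
    eligible_glut1: bool
    reasons: list[str] = field(default_factory=list)


def call_positivity(table: CellTable, panel: PanelConfig) -> CellTable:
    """Set ``<marker>_pos`` flags from intensity thresholds.

    Explicit positivity columns already present win over recomputation
    (with a logged warning), because upstream image analysis may have
    used richer criteria than a scalar threshold.
    """
    table = table.copy()
    df = table.cells
    explicit = []
    for m in panel.markers:
        icol, pcol = panel.intensity_col(m), panel.pos_col(m)
        if pcol in df.columns:
            explicit.append(m)
            df[pcol] = df[pcol].astype(bool)
            continue
        if icol not in df.columns:
            raise KeyError(f"marker {m!r} has no intensity column {icol!r}")
        df[pcol] = df[icol].to_numpy(dtype=float) >= panel.thresholds[m]
    if explicit:
        logger.warning(
            "keeping explicit positivity columns over threshold calls: %s",
            ",".join(explicit),
        )
    return table


def assign_phenotypes(table: CellTable) -> CellTable:
    """Assign the lineage phenotype per cell.

    SOX10+ -> melanoma; CD3+SOX10- -> tcell; CD31+SOX10-CD3- ->
    endothelium; else other.  SOX10+CD3+ double positives resolve to
    melanoma (SOX10 is the lineage anchor); the conflict count is logged.
    """
    table = table.copy()
    df = table.cells
    sox = df["SOX10_pos"].to_numpy(dtype=bool)
    cd3 = df["CD3_pos"].to_numpy(dtype=bool)
    cd31 = df["CD31_pos"].to_numpy(dtype=bool)
    n_conflict = int((sox & cd3).sum())
    if n_conflict:
        logger.info("%d SOX10+CD3+ double-positives resolved to melanoma", n_conflict)
    phenotype = np.full(len(df), "other", dtype=object)
    phenotype[cd31 & ~sox & ~cd3] = "endothelium"
    phenotype[cd3 & ~sox] = "tcell"
    phenotype[sox] = "melanoma"
    df["phenotype"] = phenotype
    return table


def marker_fraction(
    table: CellTable,
    phenotype: str,
    marker: str,
    compartment: str | None = None,
) -> float:
    """Fraction of ``phenotype`` cells (optionally restricted to one
    compartment) positive for ``marker``; NaN when the denominator is
    zero."""
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    df = table.cells
    mask = table.phenotype_mask(phenotype)
    if compartment is not None:
        if compartment not in ("tumor", "peritumor", "outside"):
            raise ValueError(f"unknown compartment {compartment!r}")
        if "compartment" not in df.columns:
            raise KeyError("compartments not assigned yet")
        mask = mask & (df["compartment"] == compartment)
    n = int(mask.sum())
    if n == 0:
        return float("nan")
    return float(table.positive(marker)[mask].sum() / n)


def qc_sample(table: CellTable, meta: SampleMeta, panel: PanelConfig) -> QCReport:
    """Apply the sample-level inclusion rules."""
    n_mel = int(table.phenotype_mask("melanoma").sum())
    n_imm = int(table.phenotype_mask("tcell").sum())
    reasons: list[str] = []
    eligible_spatial = (
        n_imm >= panel.min_immune_cells and n_mel >= panel.min_melanoma_cells
    )
    if n_imm < panel.min_immune_cells:
        reasons.append(
            f"immune cells {n_imm} < minimum {panel.min_immune_cells}"
        )
    if n_mel < panel.min_melanoma_cells:
        reasons.append(
            f"melanoma cells {n_mel} < minimum {panel.min_melanoma_cells}"
        )
    dediff = "dedifferentiated" in meta.flags
    if dediff:
        reasons.append("dedifferentiated melanoma: excluded from tumor analyses")
    ery = "erythrocyte_only_glut1" in meta.flags
    if ery:
        reasons.append("GLUT1 on erythrocytes only: excluded from GLUT1 analyses")
    return QCReport(
        sample_id=meta.sample_id,
        n_melanoma=n_mel,
        n_immune=n_imm,
        eligible_spatial=eligible_spatial and not dediff,
        eligible_tumor_analysis=not dediff,
        eligible_glut1=not dediff and not ery,
        reasons=reasons,
    )


def subset_mask(table: CellTable, phenotype: str, *markers: str) -> pd.Series:
    """Boolean mask for a co-expression subset, e.g.
    ``subset_mask(t, "tcell", "GLUT3", "-GLUT1")`` for CD3+GLUT3+GLUT1-.

    A leading ``-`` on a marker name requires negativity.
    """
    mask = table.phenotype_mask(phenotype)
    for m in markers:
        if m.startswith("-"):
            mask = mask & ~table.positive(m[1:])
        else:
            mask = mask & table.positive(m)
    return mask
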
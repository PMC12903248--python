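"""Data model and I/O for per-cell tables, cohort manifests and panel config.

A *cell table* is the standard export of single-cell multiplex
immunofluorescence image analysis: one row per segmented cell with its
centroid (x, y in micrometers) and one fluorescence intensity per marker,
optionally with precomputed positivity calls.  Tables are plain CSV
(comma-separated, UTF-8, header required) so they round-trip losslessly
through text.

The cohort manifest carries the clinical annotation per sample: response
to immune checkpoint blockade (responder = progression-free survival of
at least six months), PFS in months, the progression-event flag, biopsy
site, and pathologist-assigned QC flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Markers whose positivity defines a cell lineage rather than a state.
LINEAGE_MARKERS = ("SOX10", "CD3", "CD31")
STATE_MARKERS = ("GLUT1", "GLUT3", "CA9", "HIF1A")
DEFAULT_MARKERS = LINEAGE_MARKERS + STATE_MARKERS

COMPARTMENTS = ("tumor", "peritumor", "outside")
GLUT_REGIONS = ("glut1_pos", "glut1_neg", "none")
SITES = ("lymph_node", "subcutaneous", "other")
SAMPLE_FLAGS = ("dedifferentiated", "erythrocyte_only_glut1")

RESPONDER_PFS_MONTHS = 6.0


class CellTableFormatError(ValueError):
    """A cell table or manifest violates the expected CSV schema."""


@dataclass
class PanelConfig:
    """Marker panel, positivity thresholds and analysis parameters.

    Attributes
    ----------
    markers : ordered marker names in the active panel.
    thresholds : per-marker intensity cutoff (arbitrary fluorescence
        units); a cell is positive when ``intensity >= threshold``.
    proximity_threshold_um : distance (um) defining "close proximity"
        between a query cell and its nearest target cell; default 20 um.
    min_immune_cells, min_melanoma_cells : per-sample minimum counts for
        inclusion in spatial analysis (50 immune, 100 melanoma).
    peritumor_band_um : width of the peritumoral band around tumor (um).
    fdr : false-discovery rate for Benjamini-Hochberg control.
    """

    markers: tuple[str, ...] = DEFAULT_MARKERS
    thresholds: dict[str, float] = field(
        default_factory=lambda: {m: 3.0 for m in DEFAULT_MARKERS}
    )
    proximity_threshold_um: float = 20.0
    min_immune_cells: int = 50
    min_melanoma_cells: int = 100
    peritumor_band_um: float = 200.0
    fdr: float = 0.05

    # Region-grid parameters (density-grid stand-in for a trained tissue
    # classifier; all exposed because no canonical values exist).
    grid_bin_um: float = 50.0
    tumor_bin_radius_um: float = 50.0
    glut_smooth_sigma_um: float = 25.0
    glut_region_threshold: float = 0.5
    perivascular_band_um: float = 30.0
    local_glut_radius_um: float = 50.0

    # TIL-pattern cascade cutoffs.
    til_min_density_per_mm2: float = 5.0
    til_intratumoral_min_share: float = 0.20
    til_perivascular_min_share: float = 0.70

    # Metabolic-zonation call thresholds.
    zonation_trend_min: float = 0.7
    zonation_range_min: float = 0.10

    def __post_init__(self) -> None:
        if self.proximity_threshold_um <= 0:
            raise ValueError("proximity_threshold_um must be > 0")
        if self.min_immune_cells < 1 or self.min_melanoma_cells < 1:
            raise ValueError("minimum cell counts must be >= 1")
        for m, t in self.thresholds.items():
            if t <= 0:
                raise ValueError(f"threshold for {m} must be > 0")

    def intensity_col(self, marker: str) -> str:
        return f"{marker}_intensity"

    def pos_col(self, marker: str) -> str:
        return f"{marker}_pos"

    def to_file(self, path: str | Path) -> None:
        """Write the config as a flat ``key=value`` text file."""
        lines = [f"markers={','.join(self.markers)}"]
        for m in self.markers:
            lines.append(f"threshold.{m}={self.thresholds[m]}")
        for key in (
            "proximity_threshold_um", "min_immune_cells", "min_melanoma_cells",
            "peritumor_band_um", "fdr", "grid_bin_um", "tumor_bin_radius_um",
            "glut_smooth_sigma_um", "glut_region_threshold",
            "perivascular_band_um", "local_glut_radius_um",
            "til_min_density_per_mm2", "til_intratumoral_min_share",
            "til_perivascular_min_share", "zonation_trend_min",
            "zonation_range_min",
        ):
            lines.append(f"{key}={getattr(self, key)}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "PanelConfig":
        kv: dict[str, str] = {}
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise CellTableFormatError(f"bad config line: {line!r}")
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        markers = tuple(kv.pop("markers", ",".join(DEFAULT_MARKERS)).split(","))
        thresholds = {}
        for m in markers:
            thresholds[m] = float(kv.pop(f"threshold.{m}", 3.0))
        ints = {"min_immune_cells", "min_melanoma_cells"}
        kwargs = {}
        for key, val in kv.items():
            kwargs[key] = int(val) if key in ints else float(val)
        return cls(markers=markers, thresholds=thresholds, **kwargs)


@dataclass
class SampleMeta:
    """Clinical annotation for one sample."""

    sample_id: str
    pfs_months: float
    event: bool
    site: str = "other"
    response: str | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not np.isfinite(self.pfs_months) or self.pfs_months < 0:
            raise ValueError(
                f"sample {self.sample_id}: pfs_months must be finite and >= 0"
            )
        if self.site not in SITES:
            raise ValueError(f"sample {self.sample_id}: unknown site {self.site!r}")
        unknown = set(self.flags) - set(SAMPLE_FLAGS)
        if unknown:
            raise ValueError(f"sample {self.sample_id}: unknown flags {unknown}")
        rule = response_from_pfs(self.pfs_months)
        if self.response is None:
            self.response = rule
        elif self.response != rule:
            raise ValueError(
                f"sample {self.sample_id}: response={self.response!r} contradicts "
                f"the 6-month rule for pfs={self.pfs_months}"
            )


def response_from_pfs(pfs_months: float) -> str:
    """Responder iff progression-free survival is at least six months."""
    return "responder" if pfs_months >= RESPONDER_PFS_MONTHS else "nonresponder"


@dataclass
class CellTable:
    """One sample's segmented cells, backed by a pandas DataFrame.

    Required columns: ``cell_id``, ``x``, ``y`` and one
    ``<marker>_intensity`` column per panel marker.  Positivity columns
    ``<marker>_pos`` (0/1), ``phenotype``, ``compartment`` and ``region``
    appear as the pipeline stages run.  Unknown columns are preserved.
    """

    cells: pd.DataFrame
    markers: tuple[str, ...] = DEFAULT_MARKERS

    def __post_init__(self) -> None:
        for col in ("cell_id", "x", "y"):
            if col not in self.cells.columns:
                raise CellTableFormatError(f"missing required column {col!r}")
        xy = self.cells[["x", "y"]].to_numpy()
        if len(xy) and not np.all(np.isfinite(xy)):
            bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
            raise CellTableFormatError(f"non-finite coordinate at row {bad}")
        for m in self.markers:
            col = f"{m}_intensity"
            if col in self.cells.columns and len(self.cells):
                vals = self.cells[col].to_numpy(dtype=float)
                if np.any(vals < 0):
                    raise CellTableFormatError(f"negative intensity in {col}")

    def __len__(self) -> int:
        return len(self.cells)

    def points(self, mask: pd.Series | np.ndarray | None = None) -> np.ndarray:
        """(n, 2) array of cell centroids in um."""
        df = self.cells if mask is None else self.cells[np.asarray(mask, bool)]
        return df[["x", "y"]].to_numpy(dtype=float)

    def positive(self, marker: str) -> pd.Series:
        col = f"{marker}_pos"
        if col not in self.cells.columns:
            raise KeyError(f"positivity for {marker} not called yet")
        return self.cells[col].astype(bool)

    def phenotype_mask(self, label: str) -> pd.Series:
        if "phenotype" not in self.cells.columns:
            raise KeyError("phenotypes not assigned yet")
        return self.cells["phenotype"] == label

    def copy(self) -> "CellTable":
        return CellTable(self.cells.copy(), self.markers)


def read_cell_table(path: str | Path, panel: PanelConfig) -> CellTable:
    """Read a CSV cell table, validating the schema against the panel.

    Raises :class:`CellTableFormatError` naming the offending column or
    row when the file does not conform.
    """
    df = pd.read_csv(path, dtype={"cell_id": str})
    for col in ("cell_id", "x", "y"):
        if col not in df.columns:
            raise CellTableFormatError(f"{path}: missing required column {col!r}")
    for m in panel.markers:
        if panel.intensity_col(m) not in df.columns:
            raise CellTableFormatError(
                f"{path}: missing intensity column {panel.intensity_col(m)!r}"
            )
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CellTableFormatError(
                f"{path}: non-numeric {col!r} at row {row}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise CellTableFormatError(f"{path}: missing {col!r} at row {row}")
        df[col] = coerced.astype(float)
    for m in panel.markers:
        pos = panel.pos_col(m)
        if pos in df.columns:
            df[pos] = df[pos].astype(int).astype(bool)
    return CellTable(df, panel.markers)


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a cell table to CSV; boolean columns serialize as 0/1."""
    df = table.cells.copy()
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].astype(int)
    df.to_csv(path, index=False)


def read_cohort_manifest(path: str | Path) -> list[SampleMeta]:
    """Read the cohort manifest CSV into validated sample metadata.

    The ``response`` column is optional; when present it must agree with
    the 6-month PFS rule.  Flags are semicolon-separated.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = {"sample_id", "pfs_months", "event", "site"}
    missing = required - set(df.columns)
    if missing:
        raise CellTableFormatError(f"{path}: manifest missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise CellTableFormatError(f"{path}: duplicate sample_id {dup!r}")
    metas = []
    for _, row in df.iterrows():
        flags = frozenset(
            f for f in str(row.get("flags", "") or "").split(";") if f
        ) if "flags" in df.columns and pd.notna(row.get("flags")) else frozenset()
        response = row.get("response") if "response" in df.columns else None
        if isinstance(response, float) and np.isnan(response):
            response = None
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                pfs_months=float(row["pfs_months"]),
                event=bool(int(row["event"])),
                site=str(row["site"]),
                response=response,
                flags=flags,
            )
        )
    return metas


def write_cohort_manifest(metas: Sequence[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "response": m.response,
            "pfs_months": m.pfs_months,
            "event": int(m.event),
            "site": m.site,
            "flags": ";".join(sorted(m.flags)),
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class Cohort:
    """Paired clinical metadata and cell tables for a set of samples."""

    samples: list[tuple[SampleMeta, CellTable]]

    def __post_init__(self) -> None:
        ids = [m.sample_id for m, _ in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample_ids in cohort")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def metas(self) -> list[SampleMeta]:
        return [m for m, _ in self.samples]
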
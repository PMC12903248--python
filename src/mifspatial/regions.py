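"""Tissue partitioning on cell point patterns.

A trained pixel classifier is not reproducible from a cell table, so
tumor/peritumor compartments and GLUT1+/GLUT1- tumor regions are called
on a square density grid (default 50 um bins): a bin is tumor when a
SOX10+ melanoma cell lies within ``tumor_bin_radius_um`` of its center,
peritumor when within ``peritumor_band_um`` of a tumor bin, and a tumor
bin is GLUT1-positive when its Gaussian-smoothed GLUT1+ melanoma
fraction reaches ``glut_region_threshold``.  This is deterministic and
idempotent for a fixed grid.

Metabolic zonation is called from the gradient of GLUT1+ fraction over
distance-to-vessel deciles; the tumor-infiltrating-lymphocyte (TIL)
pattern is called by a rule cascade over T-cell placement (absent /
peritumoral exclusion / perivascular exclusion / inflamed-infiltrative).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .cell_io import CellTable, PanelConfig

COMPARTMENT_CODES = {"outside": 0, "tumor": 1, "peritumor": 2}
GLUT_CODES = {"none": 0, "glut1_pos": 1, "glut1_neg": 2}
_COMP_NAMES = {v: k for k, v in COMPARTMENT_CODES.items()}
_GLUT_NAMES = {v: k for k, v in GLUT_CODES.items()}


@dataclass
class RegionGrid:
    """Square-bin label grid over one sample's bounding box."""

    bin_um: float
    x0: float
    y0: float
    nx: int
    ny: int
    compartment: np.ndarray  # (ny, nx) int8, COMPARTMENT_CODES
    glut: np.ndarray  # (ny, nx) int8, GLUT_CODES
    melanoma_count: np.ndarray  # (ny, nx)
    glut1_count: np.ndarray  # (ny, nx)
    smoothed_fraction: np.ndarray  # (ny, nx), NaN off-tumor

    def bin_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ix = np.clip(((np.asarray(x) - self.x0) // self.bin_um).astype(int), 0, self.nx - 1)
        iy = np.clip(((np.asarray(y) - self.y0) // self.bin_um).astype(int), 0, self.ny - 1)
        return ix, iy

    def centers(self) -> np.ndarray:
        """(ny*nx, 2) bin-center coordinates, row-major."""
        cx = self.x0 + (np.arange(self.nx) + 0.5) * self.bin_um
        cy = self.y0 + (np.arange(self.ny) + 0.5) * self.bin_um
        gx, gy = np.meshgrid(cx, cy)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def area_mm2(self, code: int) -> float:
        return float((self.compartment == code).sum()) * self.bin_um**2 / 1e6

    def to_frame(self) -> pd.DataFrame:
        centers = self.centers()
        return pd.DataFrame({
            "bin_x": centers[:, 0],
            "bin_y": centers[:, 1],
            "compartment": [_COMP_NAMES[c] for c in self.compartment.ravel()],
            "glut_region": [_GLUT_NAMES[c] for c in self.glut.ravel()],
            "melanoma_count": self.melanoma_count.ravel(),
            "glut1_count": self.glut1_count.ravel(),
            "smoothed_glut1_fraction": self.smoothed_fraction.ravel(),
        })


@dataclass
class ZonationResult:
    """Metabolic-zonation call for one sample.

    ``trend`` is the Spearman correlation between the distance-to-vessel
    decile index and the per-decile GLUT1+ melanoma fraction;
    ``fraction_range`` is max - min of those fractions.  The sample is
    zonal when the trend is strongly increasing and the range material.
    """

    defined: bool
    is_zonal: bool = False
    trend: float = float("nan")
    fraction_range: float = float("nan")
    reason: str = ""


@dataclass
class TilPatternCall:
    """Automated TIL pattern: 0 absent, 1 peritumoral exclusion,
    2 perivascular exclusion, 3 inflamed/infiltrative."""

    pattern: int
    density_per_mm2: float
    intratumoral_share: float
    perivascular_share: float


def classify_compartments(
    table: CellTable, panel: PanelConfig
) -> tuple[CellTable, RegionGrid]:
    """Label each cell tumor / peritumor / outside via the density grid."""
    table = table.copy()
    df = table.cells
    b = panel.grid_bin_um
    if len(df) == 0:
        grid = RegionGrid(b, 0.0, 0.0, 1, 1,
                          np.zeros((1, 1), np.int8), np.zeros((1, 1), np.int8),
                          np.zeros((1, 1)), np.zeros((1, 1)),
                          np.full((1, 1), np.nan))
        df["compartment"] = pd.Series(dtype=object)
        return table, grid

    pad = panel.peritumor_band_um + b
    x0 = float(df["x"].min()) - pad
    y0 = float(df["y"].min()) - pad
    nx = int(np.ceil((float(df["x"].max()) + pad - x0) / b))
    ny = int(np.ceil((float(df["y"].max()) + pad - y0) / b))
    grid = RegionGrid(
        b, x0, y0, nx, ny,
        compartment=np.zeros((ny, nx), np.int8),
        glut=np.zeros((ny, nx), np.int8),
        melanoma_count=np.zeros((ny, nx)),
        glut1_count=np.zeros((ny, nx)),
        smoothed_fraction=np.full((ny, nx), np.nan),
    )
    centers = grid.centers()

    mel = df[df["phenotype"] == "melanoma"] if "phenotype" in df.columns else df.iloc[0:0]
    if len(mel):
        tree = cKDTree(mel[["x", "y"]].to_numpy(dtype=float))
        d_mel, _ = tree.query(centers)
        tumor = (d_mel <= panel.tumor_bin_radius_um).reshape(ny, nx)
    else:
        tumor = np.zeros((ny, nx), dtype=bool)
    grid.compartment[tumor] = COMPARTMENT_CODES["tumor"]

    if tumor.any():
        t_centers = centers[tumor.ravel()]
        d_tumor, _ = cKDTree(t_centers).query(centers)
        peri = (d_tumor <= panel.peritumor_band_um).reshape(ny, nx) & ~tumor
        grid.compartment[peri] = COMPARTMENT_CODES["peritumor"]

    ix, iy = grid.bin_index(df["x"].to_numpy(), df["y"].to_numpy())
    codes = grid.compartment[iy, ix]
    df["compartment"] = [_COMP_NAMES[c] for c in codes]

    if len(mel):
        mix, miy = grid.bin_index(mel["x"].to_numpy(), mel["y"].to_numpy())
        np.add.at(grid.melanoma_count, (miy, mix), 1.0)
        if "GLUT1_pos" in mel.columns:
            pos = mel["GLUT1_pos"].to_numpy(dtype=bool)
            np.add.at(grid.glut1_count, (miy[pos], mix[pos]), 1.0)
    return table, grid


def segment_glut_regions(
    table: CellTable, grid: RegionGrid, panel: PanelConfig
) -> tuple[CellTable, RegionGrid]:
    """Split tumor bins into GLUT1+ / GLUT1- regions.

    The per-bin GLUT1+ melanoma fraction is smoothed with a Gaussian
    kernel over tumor-bin centers (count-weighted, so sparse bins borrow
    strength from neighbors), then thresholded at
    ``glut_region_threshold``.
    """
    table = table.copy()
    df = table.cells
    tumor = grid.compartment == COMPARTMENT_CODES["tumor"]
    if not tumor.any() or grid.melanoma_count[tumor].sum() == 0:
        raise ValueError("no melanoma cells in tumor bins; sample should fail QC")
    centers = grid.centers()[tumor.ravel()]
    mel = grid.melanoma_count[tumor]
    pos = grid.glut1_count[tumor]
    sigma = panel.glut_smooth_sigma_um
    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * sigma**2))
    num = w @ pos
    den = w @ mel
    frac = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    grid.smoothed_fraction[tumor] = frac
    glut_code = np.where(
        frac >= panel.glut_region_threshold,
        GLUT_CODES["glut1_pos"], GLUT_CODES["glut1_neg"],
    )
    grid.glut[tumor] = glut_code

    ix, iy = grid.bin_index(df["x"].to_numpy(), df["y"].to_numpy())
    df["region"] = [_GLUT_NAMES[c] for c in grid.glut[iy, ix]]
    return table, grid


@dataclass
class RegionProportions:
    """Paired per-sample T-cell proportions (and per-area densities) in
    GLUT1+ vs GLUT1- tumor regions."""

    defined: bool
    prop_pos: float = float("nan")
    prop_neg: float = float("nan")
    density_pos_per_mm2: float = float("nan")
    density_neg_per_mm2: float = float("nan")
    reason: str = ""


def region_tcell_proportion(table: CellTable, grid: RegionGrid) -> RegionProportions:
    """CD3+ share of all cells in each GLUT1 region (primary), plus
    T-cells per mm^2 of region area (secondary)."""
    df = table.cells
    if "region" not in df.columns:
        raise KeyError("regions not segmented yet")
    out = {}
    dens = {}
    for label, code in (("glut1_pos", 1), ("glut1_neg", 2)):
        in_region = df["region"] == label
        n_all = int(in_region.sum())
        n_t = int((in_region & (df["phenotype"] == "tcell")).sum())
        area = float((grid.glut == code).sum()) * grid.bin_um**2 / 1e6
        if n_all == 0 or area == 0:
            return RegionProportions(False, reason=f"region {label} empty")
        out[label] = n_t / n_all
        dens[label] = n_t / area
    return RegionProportions(
        True,
        prop_pos=out["glut1_pos"], prop_neg=out["glut1_neg"],
        density_pos_per_mm2=dens["glut1_pos"],
        density_neg_per_mm2=dens["glut1_neg"],
    )


def call_metabolic_zonation(
    table: CellTable,
    panel: PanelConfig,
    vessel_points: np.ndarray | None = None,
    marker: str = "GLUT1",
    n_bins: int = 10,
) -> ZonationResult:
    """Call zonation from the marker+ melanoma fraction over
    distance-to-vessel deciles.

    Zonal means the fraction increases with distance from vessels
    (Spearman trend >= ``zonation_trend_min``) with a material dynamic
    range (>= ``zonation_range_min``).
    """
    df = table.cells
    mel = df[df["phenotype"] == "melanoma"]
    if vessel_points is None:
        vessel_points = df.loc[df["phenotype"] == "endothelium", ["x", "y"]].to_numpy(dtype=float)
    if len(mel) < 10:
        return ZonationResult(False, reason="fewer than 10 melanoma cells")
    if len(vessel_points) == 0:
        return ZonationResult(False, reason="no vessels")
    d, _ = cKDTree(vessel_points).query(mel[["x", "y"]].to_numpy(dtype=float))
    pos = mel[f"{marker}_pos"].to_numpy(dtype=bool)
    edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return ZonationResult(False, reason="degenerate distance distribution")
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, len(edges) - 2)
    fracs = np.array([
        pos[which == i].mean() if (which == i).any() else np.nan
        for i in range(len(edges) - 1)
    ])
    ok = ~np.isnan(fracs)
    if ok.sum() < 3:
        return ZonationResult(False, reason="too few occupied distance bins")
    idx = np.flatnonzero(ok)
    rho = stats.spearmanr(idx, fracs[idx]).statistic
    if np.isnan(rho):  # constant fractions
        rho = 0.0
    rng_ = float(np.nanmax(fracs) - np.nanmin(fracs))
    is_zonal = bool(rho >= panel.zonation_trend_min and rng_ >= panel.zonation_range_min)
    return ZonationResult(True, is_zonal=is_zonal, trend=float(rho), fraction_range=rng_)


def classify_til_pattern(
    table: CellTable,
    grid: RegionGrid,
    panel: PanelConfig,
    vessel_points: np.ndarray | None = None,
) -> TilPatternCall:
    """Rule cascade over T-cell placement.

    0 when tumor+peritumor CD3 density < ``til_min_density_per_mm2``;
    1 when the intratumoral share of CD3 cells < 20%; 2 when >= 70% of
    intratumoral CD3 cells sit within the perivascular band of a CD31+
    cell; else 3.
    """
    df = table.cells
    tcell = df["phenotype"] == "tcell"
    if vessel_points is None:
        vessel_points = df.loc[df["phenotype"] == "endothelium", ["x", "y"]].to_numpy(dtype=float)
    area = grid.area_mm2(COMPARTMENT_CODES["tumor"]) + grid.area_mm2(COMPARTMENT_CODES["peritumor"])
    in_tp = tcell & df["compartment"].isin(["tumor", "peritumor"])
    density = float(in_tp.sum()) / area if area > 0 else 0.0

    n_t = int(tcell.sum())
    n_intra = int((tcell & (df["compartment"] == "tumor")).sum())
    share = n_intra / n_t if n_t else 0.0

    peri_share = 0.0
    if n_intra and len(vessel_points):
        intra_xy = df.loc[tcell & (df["compartment"] == "tumor"), ["x", "y"]].to_numpy(dtype=float)
        d, _ = cKDTree(vessel_points).query(intra_xy)
        peri_share = float(np.mean(d <= panel.perivascular_band_um))

    if density < panel.til_min_density_per_mm2:
        pattern = 0
    elif share < panel.til_intratumoral_min_share:
        pattern = 1
    elif peri_share >= panel.til_perivascular_min_share:
        pattern = 2
    else:
        pattern = 3
    return TilPatternCall(pattern, density, share, peri_share)


def export_region_grid(grid: RegionGrid, path: str | Path) -> None:
    """Write the bin labels as CSV for external visualization."""
    grid.to_frame().to_csv(path, index=False)
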
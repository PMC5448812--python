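"""AFM particle volumetrics and oligomer classification.

Particles in an AFM height map are segmented above a robust background
threshold, their volumes integrated from the background-subtracted heights,
and each particle classified by volume window into sub-threshold speckle,
monomer, dimer, or multimer. The dimer window follows the convention of
volume-calibrated AFM of MutL-family complexes: particles between 170 and
350 nm^3 (inclusive) are dimers.

The expected condensed-phase volume of a protein of molecular weight M0 is

    V_c = (M0 / N0) (V1 + d V2)

with N0 Avogadro's number, V1 = 0.74 cm^3/g the protein partial specific
volume, V2 = 1 cm^3/g that of water, and d = 0.4 g water per g protein the
hydration extent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.constants
from skimage import measure, segmentation

from .stats import TestResult, g_test

__all__ = [
    "DIMER_WINDOW_NM3",
    "MONOMER_FLOOR_NM3",
    "CONFIGURATIONS",
    "HeightMap",
    "VolumeModel",
    "ParticleMeasurement",
    "ConfigurationCounts",
    "predicted_volume",
    "segment_particles",
    "measure_and_classify",
    "class_fractions",
    "compare_configurations",
]

#: Dimer volume window, nm^3, inclusive on both bounds.
DIMER_WINDOW_NM3 = (170.0, 350.0)
#: Particles below this volume are treated as noise speckles.
MONOMER_FLOOR_NM3 = 40.0

#: Shape-scored configurations of dimeric particles (scored manually
#: upstream; this module only compares their count distributions).
CONFIGURATIONS = ("extended", "one-arm folded", "semi-condensed", "condensed")


@dataclass
class HeightMap:
    """A rectangular AFM height image in nm, with its pixel size."""

    heights: np.ndarray  # (rows, cols), nm
    pixel_size_nm: float

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("height map must be a 2-D grid")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")

    @classmethod
    def from_tiff(cls, path, pixel_size_nm: float) -> "HeightMap":
        import tifffile

        return cls(tifffile.imread(str(path)), pixel_size_nm)

    @classmethod
    def from_text(cls, path, pixel_size_nm: float | None = None) -> "HeightMap":
        """Read a whitespace-delimited matrix; pixel size from arg or a JSON
        sidecar ``<path>.json`` with key ``pixel_size_nm``."""
        path = Path(path)
        if pixel_size_nm is None:
            with open(path.with_suffix(path.suffix + ".json")) as fh:
                pixel_size_nm = json.load(fh)["pixel_size_nm"]
        return cls(np.loadtxt(path), float(pixel_size_nm))

    @property
    def pixel_area_nm2(self) -> float:
        return self.pixel_size_nm**2


@dataclass(frozen=True)
class VolumeModel:
    """Parameters of the condensed-volume prediction V_c = (M0/N0)(V1 + d V2)."""

    m0_da: float
    v1_cm3_per_g: float = 0.74
    v2_cm3_per_g: float = 1.0
    hydration_g_per_g: float = 0.4
    n0: float = scipy.constants.Avogadro

    def __post_init__(self):
        if self.m0_da < 0 or min(self.v1_cm3_per_g, self.v2_cm3_per_g, self.n0) <= 0:
            raise ValueError("volume model parameters must be positive")


_CM3_TO_NM3 = 1e21


def predicted_volume(model: VolumeModel | float) -> float:
    """Predicted particle volume in nm^3 from molecular weight.

    Accepts a :class:`VolumeModel` or a bare molecular weight in Da (the
    default specific volumes and hydration then apply).
    """
    if not isinstance(model, VolumeModel):
        model = VolumeModel(m0_da=float(model))
    if model.m0_da == 0:
        return 0.0
    if model.m0_da < 0:
        raise ValueError("molecular weight must be non-negative")
    v_cm3 = (model.m0_da / model.n0) * (
        model.v1_cm3_per_g + model.hydration_g_per_g * model.v2_cm3_per_g
    )
    return v_cm3 * _CM3_TO_NM3


@dataclass
class ParticleMeasurement:
    """One segmented particle."""

    label: int
    centroid_px: tuple[float, float]  # (row, col)
    area_nm2: float
    volume_nm3: float
    oligomer_class: str
    edge_flag: bool


def _robust_background(heights: np.ndarray, threshold_sigma: float, n_iter: int = 2):
    """Plane-fit + median background with a MAD-based robust SD.

    The plane is refitted on below-threshold pixels so that particles do not
    tilt the background estimate; adding any constant plane to the image
    therefore leaves the background-subtracted heights unchanged.
    """
    rows, cols = np.indices(heights.shape)
    design = np.column_stack(
        [np.ones(heights.size), rows.ravel(), cols.ravel()]
    )
    mask = np.ones(heights.size, dtype=bool)
    flat = heights.ravel()
    for _ in range(n_iter + 1):
        coef, *_ = np.linalg.lstsq(design[mask], flat[mask], rcond=None)
        residual = flat - design @ coef
        med = np.median(residual[mask])
        rsd = 1.4826 * np.median(np.abs(residual[mask] - med))
        cutoff = med + threshold_sigma * max(rsd, 1e-12)
        mask = residual < cutoff
        if not mask.any():  # pathological: everything above threshold
            mask = np.ones(heights.size, dtype=bool)
            break
    corrected = (residual - med).reshape(heights.shape)
    return corrected, float(rsd)


def segment_particles(
    hmap: HeightMap,
    threshold_sigma: float = 3.0,
    min_area_px: int = 4,
    dilation_px: int = 3,
    class_windows=None,
) -> list[ParticleMeasurement]:
    """Segment and measure particles in a height map.

    Background is a least-squares plane (iteratively refitted on background
    pixels) plus a median offset; pixels more than ``threshold_sigma`` robust
    SDs above it are grouped by 8-connectivity. For volume integration each
    particle mask is grown by ``dilation_px`` pixels (without overlapping
    neighbours) so that the sub-threshold skirt of the particle is included:

        volume = sum(height - background) * pixel_area over member pixels.

    Particles touching the image edge are flagged; downstream summaries
    exclude them because their volume is truncated by the field of view.
    """
    if hmap.heights.shape[0] < 64 or hmap.heights.shape[1] < 64:
        raise ValueError("height map must be at least 64x64 pixels")
    corrected, rsd = _robust_background(hmap.heights, threshold_sigma)
    # Absolute floor keeps plane-fit round-off (~1e-14 nm) from seeding
    # spurious components on noise-free images.
    threshold = max(threshold_sigma * rsd, 1e-6)
    binary = corrected > threshold
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        return []
    # Drop tiny detections before growing the masks.
    counts = np.bincount(labels.ravel())
    for lab in np.nonzero(counts < min_area_px)[0]:
        if lab:
            labels[labels == lab] = 0
    labels, _, _ = segmentation.relabel_sequential(labels)
    if labels.max() == 0:
        return []
    grown = segmentation.expand_labels(labels, distance=dilation_px)
    particles = []
    px_area = hmap.pixel_area_nm2
    nrow, ncol = labels.shape
    for prop in measure.regionprops(labels, intensity_image=corrected):
        lab = prop.label
        member = grown == lab
        volume = float(corrected[member].sum() * px_area)
        minr, minc, maxr, maxc = prop.bbox
        edge = minr == 0 or minc == 0 or maxr == nrow or maxc == ncol
        particles.append(
            ParticleMeasurement(
                label=lab,
                centroid_px=tuple(map(float, prop.centroid_weighted)),
                area_nm2=float(prop.area * px_area),
                volume_nm3=volume,
                oligomer_class=classify_volume(volume, class_windows),
                edge_flag=bool(edge),
            )
        )
    return particles


def classify_volume(volume_nm3: float, class_windows=None) -> str:
    """Oligomer class from a particle volume.

    Default windows: sub-threshold below 40 nm^3, monomer [40, 170), dimer
    [170, 350] (both bounds inclusive), multimer above 350 nm^3.
    """
    windows = class_windows or {
        "monomer": (MONOMER_FLOOR_NM3, DIMER_WINDOW_NM3[0]),
        "dimer": DIMER_WINDOW_NM3,
    }
    mono_lo, dimer_lo = windows["monomer"]
    dimer_lo2, dimer_hi = windows["dimer"]
    if volume_nm3 < mono_lo:
        return "sub-threshold"
    if volume_nm3 < dimer_lo2:
        return "monomer"
    if volume_nm3 <= dimer_hi:
        return "dimer"
    return "multimer"


def measure_and_classify(hmap: HeightMap, class_windows=None, **segment_kwargs):
    """Segment, measure, and classify; returns (particles, class fractions).

    Fractions are computed among non-edge particles above the speckle floor.
    """
    particles = segment_particles(hmap, class_windows=class_windows, **segment_kwargs)
    return particles, class_fractions(particles)


def class_fractions(particles) -> dict[str, float]:
    """Per-class fractions among non-edge, above-floor particles."""
    kept = [
        p for p in particles
        if not p.edge_flag and p.oligomer_class != "sub-threshold"
    ]
    fractions = {c: 0.0 for c in ("monomer", "dimer", "multimer")}
    if kept:
        for p in kept:
            fractions[p.oligomer_class] += 1
        for c in fractions:
            fractions[c] /= len(kept)
    return fractions


@dataclass(frozen=True)
class ConfigurationCounts:
    """Shape-scored dimer configuration counts for one condition."""

    counts: dict[str, int]
    condition: str = ""

    def __post_init__(self):
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_json(cls, path) -> "ConfigurationCounts":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(counts=dict(payload["counts"]), condition=payload.get("condition", ""))


def compare_configurations(a: ConfigurationCounts, b: ConfigurationCounts) -> TestResult:
    """G test of the condition-by-configuration count table.

    Configurations absent from both conditions are dropped (with reduced
    degrees of freedom) so the expected counts stay positive.
    """
    keys = [k for k in {**a.counts, **b.counts} if a.counts.get(k, 0) + b.counts.get(k, 0) > 0]
    if len(keys) < 2:
        raise ValueError("need at least two observed configurations")
    table = np.array(
        [[a.counts.get(k, 0) for k in keys], [b.counts.get(k, 0) for k in keys]]
    )
    return g_test(table)


def particles_to_tsv(particles, path) -> None:
    pd.DataFrame(
        [
            {
                "label": p.label,
                "centroid_row_px": p.centroid_px[0],
                "centroid_col_px": p.centroid_px[1],
                "area_nm2": p.area_nm2,
                "volume_nm3": p.volume_nm3,
                "class": p.oligomer_class,
                "edge": p.edge_flag,
            }
            for p in particles
        ]
    ).to_csv(path, sep="\t", index=False)
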
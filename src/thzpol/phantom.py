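"""Synthetic 2-D tissue phantoms for polarimetric THz scan simulation.

A phantom is a raster grid of tissue classes (a :class:`LabelMap`) painted
from simple shape primitives, standing in for the whole-slide pathology
ground truth of an excised breast-tumor specimen: adjacent cancerous, fatty
and fibrous (collagen) regions embedded in paraffin (block specimens) or
lying on a polymer slide (fresh specimens).

Each class carries :class:`OpticalProperties` — a complex refractive index
and, for the fibrous class, an in-plane birefringence with an effective
layer thickness.  The published record constrains only the *ordering* of
reflectivities (cancer strongest, collagen intermediate, fat weakest,
paraffin nearly transparent); the numeric defaults here are
literature-magnitude choices documented in ``docs/methods.md``.

Coordinate convention: row 0 is the top of the image, column 0 the left;
pixel centres sit at ``(row + 0.5, col + 0.5) * step_um``; in-plane angles
are measured counter-clockwise from the +x (column) axis in degrees.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


class TissueClass(enum.IntEnum):
    """Pixel classes of the phantom; integer codes are stable for export."""

    SLIDE_BACKGROUND = 0
    PARAFFIN = 1
    FAT = 2
    COLLAGEN = 3
    CANCER = 4
    MINERALIZATION = 5
    AIR_BUBBLE = 6


#: Classes whose pixels carry an in-plane optic axis.
FIBROUS_CLASSES = frozenset({TissueClass.COLLAGEN})


@dataclass(frozen=True)
class OpticalProperties:
    """Frequency-flat complex refractive index plus birefringence.

    Parameters
    ----------
    n : float
        Real refractive index, ``n >= 1``.
    kappa : float
        Extinction coefficient, ``kappa >= 0``.
    delta_n : float
        In-plane birefringence; 0 for isotropic classes.
    layer_thickness_um : float
        Effective single-pass path length through the birefringent layer,
        in micrometres.  Only meaningful when ``delta_n > 0``.
    """

    n: float
    kappa: float = 0.0
    delta_n: float = 0.0
    layer_thickness_um: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")
        if self.kappa < 0.0:
            raise ValueError(f"extinction coefficient must be >= 0, got {self.kappa}")
        if self.delta_n < 0.0:
            raise ValueError(f"birefringence must be >= 0, got {self.delta_n}")
        if self.delta_n > 0.0 and self.layer_thickness_um <= 0.0:
            raise ValueError("birefringent class needs layer_thickness_um > 0")

    @property
    def n_complex(self) -> complex:
        return complex(self.n, self.kappa)


@dataclass(frozen=True)
class Region:
    """One painted shape primitive.

    ``shape`` is ``"rectangle"``, ``"disk"`` or ``"half_plane"``; ``params``
    are physical micrometre coordinates in the pixel-centre frame:

    - rectangle: ``row_min_um, row_max_um, col_min_um, col_max_um``
    - disk: ``center_row_um, center_col_um, radius_um``
    - half_plane: ``angle_deg, offset_um`` — keeps pixels whose projection
      onto the unit normal at ``angle_deg`` (CCW from +x) is ``>= offset_um``
    """

    shape: str
    tissue: TissueClass
    params: dict[str, float]
    optic_axis_deg: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "disk", "half_plane"):
            raise ValueError(f"unknown shape primitive {self.shape!r}")
        if self.tissue in FIBROUS_CLASSES and self.optic_axis_deg is None:
            raise ValueError(f"fibrous region ({self.tissue.name}) needs optic_axis_deg")


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic recipe for a label map (painter's order: later wins)."""

    grid_rows: int
    grid_cols: int
    step_um: float = 150.0
    regions: tuple[Region, ...] = ()
    background: TissueClass = TissueClass.SLIDE_BACKGROUND
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")
        object.__setattr__(self, "regions", tuple(self.regions))


@dataclass
class LabelMap:
    """Per-pixel tissue class plus optic-axis angle for fibrous pixels.

    ``optic_axis_deg`` is NaN wherever the class is not fibrous; where
    defined it is reduced modulo 180.
    """

    classes: np.ndarray
    optic_axis_deg: np.ndarray
    step_um: float

    def __post_init__(self) -> None:
        if self.classes.shape != self.optic_axis_deg.shape:
            raise ValueError("classes and optic_axis_deg shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    def mask(self, classes) -> np.ndarray:
        codes = [int(c) for c in classes]
        return np.isin(self.classes, codes)


def _membership(region: Region, rr_um: np.ndarray, cc_um: np.ndarray) -> np.ndarray:
    p = region.params
    if region.shape == "rectangle":
        return (
            (rr_um >= p["row_min_um"]) & (rr_um <= p["row_max_um"])
            & (cc_um >= p["col_min_um"]) & (cc_um <= p["col_max_um"])
        )
    if region.shape == "disk":
        d2 = (rr_um - p["center_row_um"]) ** 2 + (cc_um - p["center_col_um"]) ** 2
        return d2 <= p["radius_um"] ** 2
    # half_plane: x = col axis, y points up => y = -row in the CCW convention
    a = np.deg2rad(p["angle_deg"])
    proj = cc_um * np.cos(a) - rr_um * np.sin(a)
    return proj >= p["offset_um"]


def make_label_map(spec: PhantomSpec) -> LabelMap:
    """Paint the regions of ``spec`` onto the grid, later regions on top.

    Deterministic given the spec (the seed is carried for future jittered
    boundaries; painting itself is exact).  A region covering zero pixels
    raises a warning, not an error.
    """
    rows, cols = spec.grid_rows, spec.grid_cols
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr_um = (rr + 0.5) * spec.step_um
    cc_um = (cc + 0.5) * spec.step_um

    classes = np.full((rows, cols), int(spec.background), dtype=np.uint8)
    axis = np.full((rows, cols), np.nan)

    for i, region in enumerate(spec.regions):
        inside = _membership(region, rr_um, cc_um)
        if not inside.any():
            warnings.warn(
                f"region {i} ({region.shape}, {region.tissue.name}) covers no pixels",
                stacklevel=2,
            )
            continue
        classes[inside] = int(region.tissue)
        if region.tissue in FIBROUS_CLASSES:
            axis[inside] = float(region.optic_axis_deg) % 180.0
        else:
            axis[inside] = np.nan

    return LabelMap(classes=classes, optic_axis_deg=axis, step_um=spec.step_um)


# Default optical constants.  Only the ordering n(mineralization) > n(cancer)
# > n(collagen) > n(fat) > n(paraffin) and the higher extinction of fresh
# (hydrated) tissue are externally constrained; magnitudes follow published
# THz tissue-parameter surveys.  Fresh specimens sit on a Tsurupica slide
# (n ~ 1.52); FFPE blocks are dehydrated and low-loss.
_BLOCK_OPTICS: dict[TissueClass, OpticalProperties] = {
    TissueClass.SLIDE_BACKGROUND: OpticalProperties(n=1.52, kappa=0.0),
    TissueClass.PARAFFIN: OpticalProperties(n=1.50, kappa=0.005),
    TissueClass.FAT: OpticalProperties(n=1.55, kappa=0.01),
    TissueClass.COLLAGEN: OpticalProperties(
        n=1.75, kappa=0.02, delta_n=0.05, layer_thickness_um=100.0
    ),
    TissueClass.CANCER: OpticalProperties(n=1.95, kappa=0.03),
    TissueClass.MINERALIZATION: OpticalProperties(n=2.20, kappa=0.03),
    TissueClass.AIR_BUBBLE: OpticalProperties(n=1.0, kappa=0.0),
}

_FRESH_OPTICS: dict[TissueClass, OpticalProperties] = {
    TissueClass.SLIDE_BACKGROUND: OpticalProperties(n=1.52, kappa=0.0),
    TissueClass.PARAFFIN: OpticalProperties(n=1.50, kappa=0.01),
    TissueClass.FAT: OpticalProperties(n=1.60, kappa=0.15),
    TissueClass.COLLAGEN: OpticalProperties(
        n=1.90, kappa=0.30, delta_n=0.05, layer_thickness_um=100.0
    ),
    TissueClass.CANCER: OpticalProperties(n=2.10, kappa=0.40),
    TissueClass.MINERALIZATION: OpticalProperties(n=2.30, kappa=0.40),
    TissueClass.AIR_BUBBLE: OpticalProperties(n=1.0, kappa=0.0),
}

_MEDIA = {"block": _BLOCK_OPTICS, "fresh": _FRESH_OPTICS}


def default_optics(class_name: TissueClass | str, medium: str = "block") -> OpticalProperties:
    """Documented default optical constants for one tissue class.

    ``medium`` is ``"block"`` (FFPE, dehydrated, low loss) or ``"fresh"``
    (hydrated, strongly absorbing).  Unknown classes or media raise a
    ``ValueError`` naming the offender.
    """
    if medium not in _MEDIA:
        raise ValueError(f"unknown medium {medium!r}; expected 'fresh' or 'block'")
    if isinstance(class_name, str):
        try:
            class_name = TissueClass[class_name.upper()]
        except KeyError:
            raise ValueError(f"unknown tissue class {class_name!r}") from None
    if class_name not in _MEDIA[medium]:
        raise ValueError(f"unknown tissue class {class_name!r}")
    return _MEDIA[medium][class_name]


def default_optics_map(medium: str = "block") -> dict[TissueClass, OpticalProperties]:
    """Defaults for every class at once (a shallow copy; safe to edit)."""
    if medium not in _MEDIA:
        raise ValueError(f"unknown medium {medium!r}; expected 'fresh' or 'block'")
    return dict(_MEDIA[medium])


def demo_block_phantom(
    rows: int = 24,
    cols: int = 24,
    step_um: float = 150.0,
    collagen_axis_deg: float = 40.0,
    seed: int = 0,
) -> PhantomSpec:
    """A small FFPE-block-like specimen: cancer core, fat lobes and one
    collagen band embedded in paraffin, the three tissue types adjacent."""
    h = rows * step_um
    w = cols * step_um
    regions = (
        Region("rectangle", TissueClass.FAT, dict(
            row_min_um=0.12 * h, row_max_um=0.88 * h,
            col_min_um=0.10 * w, col_max_um=0.90 * w)),
        Region("disk", TissueClass.CANCER, dict(
            center_row_um=0.45 * h, center_col_um=0.42 * w, radius_um=0.22 * min(h, w))),
        Region("rectangle", TissueClass.COLLAGEN, dict(
            row_min_um=0.58 * h, row_max_um=0.74 * h,
            col_min_um=0.14 * w, col_max_um=0.86 * w),
            optic_axis_deg=collagen_axis_deg),
    )
    return PhantomSpec(
        grid_rows=rows, grid_cols=cols, step_um=step_um,
        regions=regions, background=TissueClass.PARAFFIN, seed=seed,
    )


def uniform_phantom(
    tissue: TissueClass,
    rows: int = 8,
    cols: int = 8,
    step_um: float = 150.0,
    optic_axis_deg: float | None = None,
) -> PhantomSpec:
    """A single-class phantom (handy for controlled experiments)."""
    h, w = rows * step_um, cols * step_um
    region = Region(
        "rectangle", tissue,
        dict(row_min_um=0.0, row_max_um=h, col_min_um=0.0, col_max_um=w),
        optic_axis_deg=optic_axis_deg,
    )
    return PhantomSpec(grid_rows=rows, grid_cols=cols, step_um=step_um,
                       regions=(region,), background=tissue
                       if tissue not in FIBROUS_CLASSES else TissueClass.PARAFFIN)


def export_label_map(labels: LabelMap, tiff_path, legend_csv_path) -> None:
    """Write the class grid as an 8-bit indexed TIFF plus a CSV legend."""
    tifffile.imwrite(str(tiff_path), labels.classes.astype(np.uint8))
    with open(legend_csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class_id", "name"])
        for cls in TissueClass:
            writer.writerow([int(cls), cls.name.lower()])


def rotate_label_map(labels: LabelMap, rotation_deg: float) -> LabelMap:
    """Rotate the map CCW about its centre (nearest-neighbour resampling)
    and add ``rotation_deg`` to every defined optic axis (mod 180).

    Pixels rotated in from outside the frame become SLIDE_BACKGROUND.
    """
    from scipy import ndimage

    if rotation_deg % 360.0 == 0.0:
        return replace(labels)
    # image-convention CCW = ndimage.rotate with positive angle on (row, col)
    # arrays viewed with row 0 at top requires the sign flip
    classes = ndimage.rotate(
        labels.classes, -rotation_deg, reshape=False, order=0,
        mode="constant", cval=int(TissueClass.SLIDE_BACKGROUND),
    ).astype(np.uint8)
    axis = ndimage.rotate(
        labels.optic_axis_deg, -rotation_deg, reshape=False, order=0,
        mode="constant", cval=np.nan,
    )
    fibrous = np.isin(classes, [int(c) for c in FIBROUS_CLASSES])
    axis = np.where(fibrous, (axis + rotation_deg) % 180.0, np.nan)
    return LabelMap(classes=classes, optic_axis_deg=axis, step_um=labels.step_um)
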
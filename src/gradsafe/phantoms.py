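"""Synthetic voxel body models for induced-field dosimetry.

Generates homogeneous validation cylinders and reduced heterogeneous torso
phantoms (torso bulk, two lungs, myocardial shell, blood pool) on uniform
isotropic grids.  Partial-volume voxels are assigned by center-point
membership in the innermost enclosing shape, which deliberately produces
hexahedral staircasing at conductivity interfaces.

Coordinate convention: right-handed, z along the bore axis, isocenter at
the origin.  Positions and geometry are in meters; voxel spacing in mm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TissueTable",
    "VoxelModel",
    "BodyParams",
    "DegenerateGeometryError",
    "GeometryConflictError",
    "SIGMA_MYOCARDIUM",
    "SIGMA_LUNG",
    "SIGMA_BLOOD",
    "SIGMA_TORSO_BULK",
    "LABEL_AIR",
    "LABEL_BULK",
    "LABEL_LUNG",
    "LABEL_MYOCARDIUM",
    "LABEL_BLOOD",
    "make_homogeneous_cylinder",
    "make_torso_phantom",
    "make_population",
    "anthropometric_ranges",
]

# Low-frequency tissue conductivities (S/m).  Torso bulk is a free choice
# standing in for the average of the remaining soft tissues.
SIGMA_MYOCARDIUM = 0.385
SIGMA_LUNG = 0.101
SIGMA_BLOOD = 0.662
SIGMA_TORSO_BULK = 0.23

LABEL_AIR = 0
LABEL_BULK = 1
LABEL_LUNG = 2
LABEL_MYOCARDIUM = 3
LABEL_BLOOD = 4


class DegenerateGeometryError(ValueError):
    """Grid resolution too coarse for the requested geometry."""


class GeometryConflictError(ValueError):
    """Nested organ shapes overlap or escape their container."""


@dataclass(frozen=True)
class TissueTable:
    """Mapping from integer voxel labels to tissue names and conductivities."""

    entries: tuple[tuple[int, str, float], ...]

    def __post_init__(self) -> None:
        labels = [e[0] for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in tissue table")
        for lab, name, sigma in self.entries:
            if lab < 0:
                raise ValueError(f"negative label {lab}")
            if sigma < 0:
                raise ValueError(f"negative conductivity for {name!r}")
        by_label = dict((e[0], e) for e in self.entries)
        if 0 in by_label and by_label[0][2] != 0.0:
            raise ValueError("label 0 is reserved for air and must have sigma 0")

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(e[0] for e in self.entries)

    def sigma_of(self, label: int) -> float:
        for lab, _, sigma in self.entries:
            if lab == label:
                return sigma
        raise KeyError(label)

    def sigma_lookup(self, max_label: int | None = None) -> np.ndarray:
        """Dense lookup array mapping label -> sigma (S/m)."""
        n = (max_label if max_label is not None else max(self.labels)) + 1
        table = np.zeros(n, dtype=np.float64)
        for lab, _, sigma in self.entries:
            table[lab] = sigma
        return table


DEFAULT_TISSUES = TissueTable(
    entries=(
        (LABEL_AIR, "air", 0.0),
        (LABEL_BULK, "torso_bulk", SIGMA_TORSO_BULK),
        (LABEL_LUNG, "lung", SIGMA_LUNG),
        (LABEL_MYOCARDIUM, "myocardium", SIGMA_MYOCARDIUM),
        (LABEL_BLOOD, "blood", SIGMA_BLOOD),
    )
)


@dataclass
class VoxelModel:
    """Labeled conductivity grid with named anatomical masks.

    ``labels`` is a 3-D int16 array indexed [ix, iy, iz]; ``spacing`` is the
    isotropic voxel edge length in mm; ``origin`` is the position (m) of the
    corner of voxel (0, 0, 0) in isocenter coordinates.
    """

    labels: np.ndarray
    spacing: float  # mm, isotropic
    origin: np.ndarray  # (3,) m
    tissues: TissueTable
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D")
        if not (0.1 < self.spacing < 10.0):
            raise ValueError(f"spacing {self.spacing} mm outside (0.1, 10) mm")
        present = set(np.unique(self.labels).tolist())
        if not present <= set(self.tissues.labels):
            raise ValueError(f"labels {present - set(self.tissues.labels)} missing from tissue table")
        for mname, mask in self.masks.items():
            if mask.shape != self.labels.shape:
                raise ValueError(f"mask {mname!r} shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def spacing_m(self) -> float:
        return self.spacing * 1e-3

    def sigma_grid(self) -> np.ndarray:
        """Conductivity (S/m) per voxel."""
        return self.tissues.sigma_lookup(int(self.labels.max()))[self.labels]

    def voxel_centers(self, z_shift: float = 0.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D voxel-center coordinate arrays (m), optionally shifted along z."""
        h = self.spacing_m
        nx, ny, nz = self.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * h
        y = self.origin[1] + (np.arange(ny) + 0.5) * h
        z = self.origin[2] + (np.arange(nz) + 0.5) * h + z_shift
        return x, y, z


@dataclass(frozen=True)
class BodyParams:
    """Geometric parameters of the reduced torso phantom (all lengths m).

    When ``lung_offsets`` is None (the default), the two lungs are placed
    tangent to the (scaled) heart along ±x so that myocardium-lung voxel
    boundaries exist at any heart_scale without analytic overlap.
    """

    torso_a: float = 0.09  # axial cross-section semi-axis, x
    torso_b: float = 0.075  # semi-axis, y
    torso_length: float = 0.18
    heart_center: tuple[float, float, float] = (0.010, 0.0, 0.0)
    heart_semi_axes: tuple[float, float, float] = (0.022, 0.019, 0.022)
    wall_thickness: float = 0.0055
    lung_semi_axes: tuple[float, float, float] = (0.016, 0.024, 0.040)
    lung_offsets: tuple[tuple[float, float, float], ...] | None = None
    heart_scale: float = 1.0
    resolution: float = 2.0  # mm

    def __post_init__(self) -> None:
        lengths = (
            self.torso_a,
            self.torso_b,
            self.torso_length,
            self.wall_thickness,
            *self.heart_semi_axes,
            *self.lung_semi_axes,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths must be positive")
        if self.heart_scale <= 0:
            raise ValueError("heart_scale must be positive")
        if self.wall_thickness * self.heart_scale >= min(self.scaled_heart_semi_axes):
            raise ValueError("wall thickness must be smaller than the smallest heart semi-axis")
        if self.lung_offsets is None:
            cx, cy, cz = self.heart_center
            hx = self.scaled_heart_semi_axes[0]
            lx = self.lung_semi_axes[0]
            object.__setattr__(
                self,
                "lung_offsets",
                ((cx + hx + lx, cy, cz), (cx - hx - lx, cy, cz)),
            )
        self._check_containment()

    @property
    def scaled_heart_semi_axes(self) -> tuple[float, float, float]:
        return tuple(s * self.heart_scale for s in self.heart_semi_axes)

    def _check_containment(self) -> None:
        # Conservative corner test: ellipsoid bounding extents inside the
        # elliptical cylinder and the z range.
        def contained(center, semi):
            cx, cy, cz = center
            sx, sy, sz = semi
            in_xy = ((abs(cx) + sx) / self.torso_a) ** 2 + ((abs(cy) + sy) / self.torso_b) ** 2 <= 1.0 + 1e-12
            in_z = abs(cz) + sz <= self.torso_length / 2 + 1e-12
            return in_xy and in_z

        if not contained(self.heart_center, self.scaled_heart_semi_axes):
            raise GeometryConflictError("heart not fully inside torso")
        for off in self.lung_offsets:
            if not contained(off, self.lung_semi_axes):
                raise GeometryConflictError("lung not fully inside torso")


def _grid_axes(extent: tuple[float, float, float], resolution_mm: float, pad_voxels: int = 1):
    """Build a symmetric grid of voxel centers covering ±extent plus padding.

    Returns (origin, shape, (x, y, z) center coordinate arrays).
    """
    h = resolution_mm * 1e-3
    shape = tuple(int(np.ceil(2 * e / h)) + 2 * pad_voxels for e in extent)
    origin = np.array([-(n * h) / 2 for n in shape])
    axes = tuple(origin[i] + (np.arange(shape[i]) + 0.5) * h for i in range(3))
    return origin, shape, axes


def _inside_elliptic_cylinder(x, y, z, a, b, length):
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    return ((xx / a) ** 2 + (yy / b) ** 2 <= 1.0) & (np.abs(zz) <= length / 2)


def _inside_ellipsoid(x, y, z, center, semi):
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    return (
        ((xx - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((zz - center[2]) / semi[2]) ** 2
    ) <= 1.0


def make_homogeneous_cylinder(
    a: float,
    b: float,
    length: float,
    sigma: float,
    resolution: float,
    myocardium_fraction: float = 1.0,
) -> VoxelModel:
    """Homogeneous elliptical-cylinder conductor (validation geometry).

    Parameters
    ----------
    a, b:
        Cross-section semi-axes (m), x and y.
    length:
        Cylinder extent along z (m).
    sigma:
        Uniform conductivity (S/m).
    resolution:
        Isotropic voxel edge (mm); must give at least 8 voxels per semi-axis.
    myocardium_fraction:
        The "myocardium" mask is the conductor scaled by this factor about
        the origin (1.0 means the full conductor).
    """
    if min(a, b, length) <= 0:
        raise ValueError("a, b, length must be positive")
    h = resolution * 1e-3
    if a / h < 8 or b / h < 8:
        raise DegenerateGeometryError(
            f"resolution {resolution} mm too coarse: need >= 8 voxels per semi-axis"
        )
    origin, shape, (x, y, z) = _grid_axes((a, b, length / 2), resolution)
    inside = _inside_elliptic_cylinder(x, y, z, a, b, length)
    labels = np.where(inside, LABEL_BULK, LABEL_AIR).astype(np.int16)
    f = myocardium_fraction
    myo = _inside_elliptic_cylinder(x, y, z, f * a, f * b, f * length) & inside
    tissues = TissueTable(entries=((LABEL_AIR, "air", 0.0), (LABEL_BULK, "conductor", float(sigma))))
    return VoxelModel(
        labels=labels,
        spacing=resolution,
        origin=origin,
        tissues=tissues,
        masks={"myocardium": myo, "heart_total": myo.copy()},
        name=f"cylinder_a{a}_b{b}",
    )


def make_torso_phantom(params: BodyParams | None = None) -> VoxelModel:
    """Reduced five-tissue torso phantom.

    Nested geometry: elliptical-cylinder torso bulk, two lung ellipsoids,
    and an ellipsoidal myocardial shell around a blood-pool ellipsoid.
    Voxels take the label of the innermost shape containing their center.
    The heart is placed tangent to a lung so that myocardium-lung and
    myocardium-blood conductivity boundaries exist on the voxel grid.
    """
    p = params if params is not None else BodyParams()
    origin, shape, (x, y, z) = _grid_axes((p.torso_a, p.torso_b, p.torso_length / 2), p.resolution)

    torso = _inside_elliptic_cylinder(x, y, z, p.torso_a, p.torso_b, p.torso_length)
    outer = np.array(p.scaled_heart_semi_axes)
    inner = outer - p.wall_thickness * p.heart_scale
    heart_outer = _inside_ellipsoid(x, y, z, p.heart_center, outer)
    blood = _inside_ellipsoid(x, y, z, p.heart_center, inner)

    lungs = np.zeros(shape, dtype=bool)
    for off in p.lung_offsets:
        lungs |= _inside_ellipsoid(x, y, z, off, p.lung_semi_axes)

    if np.any(lungs & heart_outer):
        raise GeometryConflictError("lung and heart volumes overlap")

    labels = np.full(shape, LABEL_AIR, dtype=np.int16)
    labels[torso] = LABEL_BULK
    labels[lungs & torso] = LABEL_LUNG
    labels[heart_outer & torso] = LABEL_MYOCARDIUM
    labels[blood & torso] = LABEL_BLOOD

    myo = labels == LABEL_MYOCARDIUM
    if not myo.any():
        raise DegenerateGeometryError("myocardial shell resolved to zero voxels")
    heart_total = myo | (labels == LABEL_BLOOD)
    return VoxelModel(
        labels=labels,
        spacing=p.resolution,
        origin=origin,
        tissues=DEFAULT_TISSUES,
        masks={"myocardium": myo, "heart_total": heart_total},
        name=f"torso_res{p.resolution}mm_hs{p.heart_scale}",
    )


def anthropometric_ranges(
    height_m: tuple[float, float] = (1.53, 1.90),
    torso_fraction: float = 0.12,
    width_factor: tuple[float, float] = (0.9, 1.15),
    heart_scale: tuple[float, float] = (1.0, 1.22),
) -> dict[str, tuple[float, float]]:
    """Parameter ranges for a synthetic population.

    Torso length is mapped from standing height by ``torso_fraction`` (the
    phantom covers the cardiac segment of the torso, not the full body);
    cross-section semi-axes scale by ``width_factor``. The mapping is a
    documented free choice: the source ranges give heights/weights only.
    """
    base = BodyParams()
    return {
        "torso_length": (height_m[0] * torso_fraction, height_m[1] * torso_fraction),
        "torso_a": (base.torso_a * width_factor[0], base.torso_a * width_factor[1]),
        "torso_b": (base.torso_b * width_factor[0], base.torso_b * width_factor[1]),
        "heart_scale": heart_scale,
    }


def make_population(
    n: int,
    seed: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    base: BodyParams | None = None,
) -> list[VoxelModel]:
    """Draw ``n`` torso phantoms with parameters uniform over ``ranges``.

    Reproducible for a fixed seed. Infeasible ranges (any endpoint
    violating the geometry invariants) raise before any model is built.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base if base is not None else BodyParams()
    ranges = ranges if ranges is not None else anthropometric_ranges()
    valid = {f.name for f in dataclasses.fields(BodyParams)}
    for key, (lo, hi) in ranges.items():
        if key not in valid:
            raise ValueError(f"unknown BodyParams field {key!r}")
        if lo > hi:
            raise ValueError(f"empty range for {key!r}")
    # Feasibility: all corner combinations of the ranges must be valid.
    _check_range_feasibility(base, ranges)

    rng = np.random.default_rng(seed)
    models = []
    for i in range(n):
        draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in sorted(ranges.items())}
        # Re-derive lung placement for the drawn heart scale (tangent lungs).
        draw.setdefault("lung_offsets", None)
        params = replace(base, **draw)
        model = make_torso_phantom(params)
        model.name = f"pop{i:03d}"
        models.append(model)
    return models


def _check_range_feasibility(base: BodyParams, ranges: dict[str, tuple[float, float]]) -> None:
    import itertools

    keys = sorted(ranges)
    for corner in itertools.product(*([ranges[k][0], ranges[k][1]] for k in keys)):
        try:
            replace(base, lung_offsets=None, **dict(zip(keys, corner)))
        except (ValueError, GeometryConflictError) as exc:
            raise GeometryConflictError(f"infeasible parameter ranges: {exc}") from exc
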
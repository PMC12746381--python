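"""Landmark sweeps and dB/dt-over-E ratio studies.

The body model is translated along the bore (coil and compliance volume
fixed, equivalent to patient-table landmarking); the solver runs at each
landmark and the worst case per E-metric is the landmark maximizing that
metric, ties broken toward the smaller |z|. Each (model, coil, axis)
worst case contributes one ratio sample to the study distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd


from .coils import (
    CoilModel,
    ComplianceVolume,
    DriveSpec,
    IdealUniformB,
    IdealUniformGradient,
    compliance_peak_dBdt,
    gradient_efficiency,
    vector_potential_A,
)
from .em_solver import SolveConfig, solve_E
from .field_metrics import MetricSet, metric_set
from .phantoms import VoxelModel

logger = logging.getLogger(__name__)

METRIC_NAMES = ("Emax", "E99.9", "E99", "E95")

RATIO_COLUMNS = [
    "model_id",
    "coil_id",
    "axis",
    "landmark_z",
    "metric",
    "E_value",
    "peak_dBdt",
    "ratio",
]


@dataclass(frozen=True)
class SweepConfig:
    """Landmark-sweep settings."""

    landmark_step: float = 0.05  # m
    n_landmarks: int = 41
    axes: tuple[str, ...] = ("Z",)
    slew: float = 100.0  # T/m/s per axis (or total for XYZ)
    metric_names: tuple[str, ...] = METRIC_NAMES
    mask_name: str = "myocardium"
    solver: SolveConfig = field(default_factory=SolveConfig)
    z_bounds: tuple[float, float] | None = None  # world-z clamp for the body

    def __post_init__(self) -> None:
        if self.landmark_step <= 0:
            raise ValueError("landmark_step must be positive")
        if self.n_landmarks < 1:
            raise ValueError("n_landmarks must be >= 1")
        bad = set(self.metric_names) - set(METRIC_NAMES)
        if bad:
            raise ValueError(f"unknown metrics {bad}")
        bad_axes = set(self.axes) - {"X", "Y", "Z", "XYZ"}
        if bad_axes:
            raise ValueError(f"unknown axes {bad_axes}")

    def landmarks(self) -> np.ndarray:
        """Symmetric landmark offsets about isocenter (m)."""
        n = self.n_landmarks
        return (np.arange(n) - (n - 1) / 2) * self.landmark_step


@dataclass(frozen=True)
class RatioRecord:
    model_id: str
    coil_id: str
    axis: str
    landmark_z: float
    metric: str
    E_value: float  # V/m
    peak_dBdt: float  # T/s
    ratio: float  # (T/s)/(V/m)

    def __post_init__(self) -> None:
        if self.E_value <= 0:
            raise ValueError("E_value must be positive")
        if not np.isclose(self.ratio, self.peak_dBdt / self.E_value, rtol=1e-12):
            raise ValueError("ratio must equal peak_dBdt / E_value")


@dataclass
class RatioTable:
    records: list[RatioRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def append(self, rec: RatioRecord) -> None:
        key = (rec.model_id, rec.coil_id, rec.axis, rec.landmark_z, rec.metric)
        if key in self._keys():
            raise ValueError(f"duplicate ratio record key {key}")
        self.records.append(rec)

    def _keys(self) -> set:
        return {
            (r.model_id, r.coil_id, r.axis, r.landmark_z, r.metric) for r in self.records
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records], columns=RATIO_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "RatioTable":
        table = cls(provenance=provenance or {})
        for row in df.itertuples(index=False):
            table.append(
                RatioRecord(
                    model_id=row.model_id,
                    coil_id=row.coil_id,
                    axis=row.axis,
                    landmark_z=float(row.landmark_z),
                    metric=row.metric,
                    E_value=float(row.E_value),
                    peak_dBdt=float(row.peak_dBdt),
                    ratio=float(row.ratio),
                )
            )
        return table


@dataclass(frozen=True)
class CoilSet:
    """Per-axis coils of one gradient system."""

    name: str
    coils: dict[str, CoilModel] = field(default_factory=dict)

    def sources_for(self, axis: str):
        if axis == "XYZ":
            missing = {"X", "Y", "Z"} - set(self.coils)
            if missing:
                raise KeyError(f"coil set {self.name!r} lacks axes {missing}")
            return [self.coils[a] for a in ("X", "Y", "Z")]
        if axis not in self.coils:
            raise KeyError(f"coil set {self.name!r} lacks axis {axis}")
        return [self.coils[axis]]

    def default_compliance_volume(self) -> ComplianceVolume:
        if not self.coils:
            return ComplianceVolume()
        zmins, zmaxs = zip(*(c.wire_z_extent() for c in self.coils.values()))
        return ComplianceVolume(z_extent=(min(zmins), max(zmaxs)))


def _eval_dAdt(sources, slew: float, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """dA/dt (V/m) on the tensor grid x × y × z, shape (nx, ny, nz, 3)."""
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    out = np.zeros((len(pts), 3))
    src_list = sources if isinstance(sources, (list, tuple)) else [sources]
    for src in src_list:
        if isinstance(src, IdealUniformB):
            out += src.dAdt(pts).values
        elif isinstance(src, IdealUniformGradient):
            scale = slew / np.sqrt(len(src_list)) / src.gradient
            out += src.A(pts).values * scale
        else:
            g_eff = gradient_efficiency(src)
            scale = slew / np.sqrt(len(src_list)) / g_eff
            out += vector_potential_A(src, pts).values * scale
    return out.reshape((len(x), len(y), len(z), 3))


def dAdt_on_grid(sources, model: VoxelModel, slew: float, z_shift: float = 0.0) -> np.ndarray:
    """-dA/dt excitation (V/m) at every voxel center of the shifted body.

    ``sources`` is a list of per-axis coils (each driven at slew/sqrt(n),
    in phase) or a single ideal field object. Returned array has shape
    grid + (3,) and holds dA/dt (the solver negates it).
    """
    x, y, z = model.voxel_centers(z_shift=z_shift)
    return _eval_dAdt(sources, slew, x, y, z)


def _dAdt_per_landmark(sources, model: VoxelModel, slew: float, offsets: np.ndarray):
    """dA/dt grids for each landmark offset.

    When every offset is an integer number of voxels, the coil field is
    evaluated once on a z-extended grid and sliced per landmark; otherwise
    each landmark is evaluated independently.
    """
    h = model.spacing_m
    ks = np.asarray(offsets) / h
    kint = np.rint(ks).astype(int)
    if np.allclose(ks, kint, atol=1e-9) and len(offsets) > 1:
        nz = model.shape[2]
        kmin, kmax = int(kint.min()), int(kint.max())
        x, y, _ = model.voxel_centers()
        z_ext = model.origin[2] + (np.arange(kmin, nz + kmax) + 0.5) * h
        ext = _eval_dAdt(sources, slew, x, y, z_ext)
        return [ext[:, :, k - kmin : k - kmin + nz, :] for k in kint]
    return [dAdt_on_grid(sources, model, slew, z_shift=float(off)) for off in offsets]


def run_landmark_sweep(
    model: VoxelModel,
    sources,
    config: SweepConfig,
    peak_dBdt: float | None = None,
) -> tuple[list[MetricSet | None], dict[str, float]]:
    """Solve at each landmark; return per-landmark metrics and worst cases.

    Returns (metric sets, worst_case_landmark_z per metric name). Landmarks
    whose shifted body leaves ``config.z_bounds`` are skipped (None entry)
    with a logged warning.
    """
    mask = model.masks[config.mask_name]
    offsets = config.landmarks()
    keep = np.ones(len(offsets), dtype=bool)
    if config.z_bounds is not None:
        for i, z_off in enumerate(offsets):
            z0 = model.origin[2] + z_off
            z1 = z0 + model.shape[2] * model.spacing_m
            if z0 < config.z_bounds[0] or z1 > config.z_bounds[1]:
                logger.warning("landmark %+0.3f m leaves z bounds; skipped", z_off)
                keep[i] = False
    fields = _dAdt_per_landmark(sources, model, config.slew, offsets[keep])
    fields_iter = iter(fields)
    results: list[MetricSet | None] = []
    for z_off, ok in zip(offsets, keep):
        if not ok:
            results.append(None)
            continue
        dAdt = next(fields_iter)
        emap = solve_E(model, dAdt, config.solver, landmark_z=float(z_off))
        results.append(metric_set(emap, mask))
    worst = {}
    for name in config.metric_names:
        candidates = [
            (ms.value(name), off) for ms, off in zip(results, offsets) if ms is not None
        ]
        if not candidates:
            raise RuntimeError("all landmarks were skipped")
        best_val = max(v for v, _ in candidates)
        ties = [off for v, off in candidates if v == best_val]
        worst[name] = float(min(ties, key=lambda z: (abs(z), z)))
    return results, worst


def compute_ratio(peak_dBdt: float, E_value: float) -> float:
    """dB/dt-over-E conversion ratio, (T/s)/(V/m)."""
    if E_value <= 0:
        raise ValueError("E_value must be positive")
    return peak_dBdt / E_value


def run_study(
    models: list[VoxelModel],
    coil_sets: list[CoilSet],
    config: SweepConfig,
    cv: ComplianceVolume | None = None,
) -> RatioTable:
    """Cartesian sweep over models x coil sets x axes.

    For each combination, the landmark sweep is run and one ratio record
    per metric is taken at that metric's worst-case landmark. Individual
    failures are logged into the provenance and the study continues.
    """
    table = RatioTable(
        provenance={
            "config": {
                "landmark_step": config.landmark_step,
                "n_landmarks": config.n_landmarks,
                "axes": list(config.axes),
                "slew": config.slew,
                "metrics": list(config.metric_names),
            },
            "models": [m.name for m in models],
            "coil_sets": [c.name for c in coil_sets],
            "failures": [],
        }
    )
    for cs in coil_sets:
        volume = cv if cv is not None else cs.default_compliance_volume()
        for axis in config.axes:
            needed = ("X", "Y", "Z") if axis == "XYZ" else (axis,)
            if any(a not in cs.coils for a in needed):
                logger.debug("coil set %s lacks axis %s; skipped", cs.name, axis)
                continue
            try:
                sources = cs.sources_for(axis)
                drive = DriveSpec(slew=config.slew, axis_combination=tuple(axis) if axis != "XYZ" else ("X", "Y", "Z"))
                peak = compliance_peak_dBdt(sources, drive, volume)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("coil %s axis %s failed: %s", cs.name, axis, exc)
                table.provenance["failures"].append(f"{cs.name}/{axis}: {exc}")
                continue
            for model in models:
                try:
                    per_landmark, worst = run_landmark_sweep(model, sources, config)
                    offsets = list(config.landmarks())
                    for metric in config.metric_names:
                        z_star = worst[metric]
                        ms = per_landmark[offsets.index(min(offsets, key=lambda o: abs(o - z_star)))]
                        e_val = ms.value(metric)
                        table.append(
                            RatioRecord(
                                model_id=model.name,
                                coil_id=cs.name,
                                axis=axis,
                                landmark_z=z_star,
                                metric=metric,
                                E_value=e_val,
                                peak_dBdt=peak,
                                ratio=compute_ratio(peak, e_val),
                            )
                        )
                except Exception as exc:
                    logger.warning(
                        "model %s / coil %s / axis %s failed: %s", model.name, cs.name, axis, exc
                    )
                    table.provenance["failures"].append(
                        f"{model.name}/{cs.name}/{axis}: {exc}"
                    )
    return table


def aggregate_ratios(
    table: RatioTable,
    metric: str,
    percentiles: tuple[float, ...] = (0.1, 1.0, 10.0),
    bins: int = 50,
) -> dict:
    """Worst case (min), nearest-rank percentiles, and histogram of ratios."""
    ratios = np.array([r.ratio for r in table.records if r.metric == metric])
    if ratios.size == 0:
        raise ValueError(f"no records for metric {metric!r}")
    srt = np.sort(ratios)
    out = {
        "metric": metric,
        "n": int(ratios.size),
        "worst_case": float(srt[0]),
        "percentiles": {},
    }
    for p in percentiles:
        rank = max(1, int(np.ceil(p * len(srt) / 100.0)))
        out["percentiles"][p] = float(srt[rank - 1])
    counts, edges = np.histogram(ratios, bins=bins)
    out["histogram"] = {"counts": counts.tolist(), "edges": edges.tolist()}
    return out
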
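"""Wire-loop gradient-coil models and quasi-static field evaluation.

Coils are sets of closed polylines with signed currents. B and the vector
potential A are evaluated with the exact finite straight-segment closed
forms (Coulomb gauge), summed over segments — no numerical quadrature.
Idealized per-axis generators provide a Maxwell pair (Z) and a Golay
saddle set (X/Y), optionally with concentric shield windings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MU0 = 4e-7 * np.pi

# Realistic whole-body geometry envelope for presets (m).
REALISTIC_ID_RANGE = (0.64, 0.92)
REALISTIC_LENGTH_RANGE = (1.06, 1.60)

_EPS_WIRE = 1e-3  # minimum point-to-segment distance (m)


class SingularEvaluationError(ValueError):
    """A field point lies within the exclusion distance of a wire segment."""


@dataclass(frozen=True)
class Loop:
    """Closed polyline carrying a signed current (A-turns)."""

    vertices: np.ndarray  # (n, 3) m; implicitly closed (last connects to first)
    current: float

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 3:
            raise ValueError("loop needs >= 3 vertices of dimension 3")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite loop coordinates")
        # Drop an explicit duplicate closing vertex.
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        object.__setattr__(self, "vertices", v)

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Segment start and end points, (n, 3) each, closing the loop."""
        starts = self.vertices
        ends = np.roll(self.vertices, -1, axis=0)
        return starts, ends


@dataclass
class CoilModel:
    """A gradient-coil axis as a set of current loops.

    ``inner_diameter`` and ``length`` are geometric metadata (m); presets
    enforce the realistic ranges unless ``allow_unrealistic`` was set.
    """

    loops: list[Loop]
    axis: str  # "X" | "Y" | "Z"
    inner_diameter: float
    length: float
    name: str = "coil"

    def __post_init__(self) -> None:
        if self.axis not in ("X", "Y", "Z"):
            raise ValueError(f"axis must be X, Y or Z, got {self.axis!r}")
        if not self.loops:
            raise ValueError("coil has no loops")

    def scaled(self, factor: float) -> "CoilModel":
        """Same geometry with all currents multiplied by ``factor``."""
        loops = [Loop(l.vertices, l.current * factor) for l in self.loops]
        return CoilModel(loops, self.axis, self.inner_diameter, self.length, self.name)

    def wire_z_extent(self) -> tuple[float, float]:
        zs = np.concatenate([l.vertices[:, 2] for l in self.loops])
        return float(zs.min()), float(zs.max())


@dataclass(frozen=True)
class FieldSamples:
    """Vector field values at sample points.

    kind: "B" (tesla), "A" (tesla·meter) or "dAdt" (volt/meter).
    """

    points: np.ndarray  # (n, 3) m
    values: np.ndarray  # (n, 3)
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("B", "A", "dAdt"):
            raise ValueError(f"unknown field kind {self.kind!r}")
        if self.points.shape != self.values.shape:
            raise ValueError("points/values shape mismatch")


@dataclass(frozen=True)
class ComplianceVolume:
    """Cylinder along the bore over which peak dB/dt is evaluated."""

    radius: float = 0.20
    z_extent: tuple[float, float] = (-0.5, 0.5)
    spacing: float = 0.01  # sample spacing, m

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.z_extent[0] >= self.z_extent[1]:
            raise ValueError("z_min must be < z_max")
        if self.spacing <= 0 or self.spacing > 0.01 + 1e-12:
            raise ValueError("sample spacing must be in (0, 1 cm]")

    def sample_points(self, boundary_only: bool = True) -> np.ndarray:
        """Sample points of the cylinder at the configured spacing, (n, 3).

        With ``boundary_only`` (default) only the side surface and end
        disks are sampled: every component of B is harmonic in the
        source-free bore, so |B|^2 is subharmonic and attains its maximum
        on the cylinder boundary. Pass False for the full volume grid.
        """
        r, h = self.radius, self.spacing
        xs = np.arange(-r, r + h / 2, h)
        zs = np.arange(self.z_extent[0], self.z_extent[1] + h / 2, h)
        xx, yy = np.meshgrid(xs, xs, indexing="ij")
        keep = xx**2 + yy**2 <= r**2 + 1e-15
        xy = np.column_stack([xx[keep], yy[keep]])
        if boundary_only:
            nphi = max(8, int(np.ceil(2 * np.pi * r / h)))
            phi = 2 * np.pi * np.arange(nphi) / nphi
            side = np.empty((nphi * len(zs), 3))
            side[:, 0] = np.repeat(r * np.cos(phi), len(zs))
            side[:, 1] = np.repeat(r * np.sin(phi), len(zs))
            side[:, 2] = np.tile(zs, nphi)
            caps = np.empty((2 * len(xy), 3))
            caps[: len(xy), :2] = xy
            caps[: len(xy), 2] = zs[0]
            caps[len(xy) :, :2] = xy
            caps[len(xy) :, 2] = zs[-1]
            pts = np.vstack([side, caps])
        else:
            pts = np.empty((len(xy) * len(zs), 3))
            pts[:, :2] = np.repeat(xy, len(zs), axis=0)
            pts[:, 2] = np.tile(zs, len(xy))
        if pts.size == 0:
            raise ValueError("empty compliance sample grid")
        return pts


@dataclass(frozen=True)
class DriveSpec:
    """Sinusoidal gradient drive at peak slew (per-axis T/m/s)."""

    slew: float = 100.0
    frequency: float = 1000.0
    axis_combination: tuple[str, ...] = ("Z",)
    combination_rule: str = "rss"  # simultaneous in-phase drive at slew/sqrt(n)

    def __post_init__(self) -> None:
        if self.slew <= 0:
            raise ValueError("slew must be positive")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.combination_rule not in ("rss",):
            raise ValueError(f"unknown combination rule {self.combination_rule!r}")

    def per_axis_slew(self) -> float:
        return self.slew / np.sqrt(len(self.axis_combination))


def _gather_segments(coil: CoilModel):
    starts, ends, currents = [], [], []
    for loop in coil.loops:
        s, e = loop.segments()
        starts.append(s)
        ends.append(e)
        currents.append(np.full(len(s), loop.current))
    return np.vstack(starts), np.vstack(ends), np.concatenate(currents)


def _segment_loop_index(coil: CoilModel, seg_index: int) -> int:
    count = 0
    for i, loop in enumerate(coil.loops):
        count += len(loop.vertices)
        if seg_index < count:
            return i
    return len(coil.loops) - 1


def _segment_fields(points, starts, ends, currents, want_B: bool, coil: CoilModel):
    """Sum finite-segment closed forms over all segments at all points.

    B: Hanson-Hirshman form  B = (mu0 I/4pi) (Ri+Rf)(Ri x Rf) /
       (Ri Rf (Ri Rf + Ri.Rf)); A: (mu0 I/4pi) e_hat ln[(Ri+Rf+L)/(Ri+Rf-L)].
    The minimum point-to-segment clearance is enforced in the same pass.
    """
    out = np.zeros_like(points)
    seg = ends - starts
    L = np.linalg.norm(seg, axis=1)
    seg_len2 = L**2
    ehat = seg / L[:, None]
    nseg = len(starts)
    # Bounding-box prefilter: when every segment clears the points' bounding
    # box by more than the wire-exclusion distance, the exact per-point
    # clearance test is unnecessary.
    p_lo, p_hi = points.min(axis=0), points.max(axis=0)
    s_lo = np.minimum(starts, ends)
    s_hi = np.maximum(starts, ends)
    gaps = np.maximum(0.0, np.maximum(p_lo - s_hi, s_lo - p_hi))
    far = np.einsum("ij,ij->i", gaps, gaps) > _EPS_WIRE**2
    # Keep per-chunk (points x segments x 3) temporaries around ~25 MB.
    chunk = max(1, int(1e6 // max(len(points), 1)) if len(points) > 1000 else nseg)
    for lo in range(0, nseg, chunk):
        hi = min(lo + chunk, nseg)
        ri = points[:, None, :] - starts[None, lo:hi, :]  # (p, s, 3)
        rf = points[:, None, :] - ends[None, lo:hi, :]
        Ri = np.linalg.norm(ri, axis=2)
        Rf = np.linalg.norm(rf, axis=2)
        if not far[lo:hi].all():
            # Clearance: exact point-segment distance.
            t = np.clip(np.einsum("psk,sk->ps", ri, seg[lo:hi]) / seg_len2[lo:hi], 0.0, 1.0)
            nearest = ri - t[:, :, None] * seg[None, lo:hi, :]
            dist2 = np.einsum("psk,psk->ps", nearest, nearest)
            if dist2.min() < _EPS_WIRE**2:
                s_idx = int(np.unravel_index(np.argmin(dist2), dist2.shape)[1]) + lo
                raise SingularEvaluationError(
                    f"field point within {_EPS_WIRE*1e3:.0f} mm of wire segment "
                    f"{s_idx} (loop {_segment_loop_index(coil, s_idx)})"
                )
        if want_B:
            cross = np.cross(ri, rf)
            denom = Ri * Rf * (Ri * Rf + np.einsum("psk,psk->ps", ri, rf))
            coef = currents[lo:hi] * (Ri + Rf) / denom
            out += np.einsum("ps,psk->pk", coef, cross)
        else:
            s = Ri + Rf
            val = np.log((s + L[lo:hi]) / (s - L[lo:hi]))
            out += np.einsum("ps,sk->pk", currents[lo:hi] * val, ehat[lo:hi])
    return out * (MU0 / (4 * np.pi))


def biot_savart_B(coil: CoilModel, points: np.ndarray) -> FieldSamples:
    """Magnetic flux density (T) of the coil at the given points."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    starts, ends, currents = _gather_segments(coil)
    values = _segment_fields(points, starts, ends, currents, want_B=True, coil=coil)
    return FieldSamples(points=points, values=values, kind="B")


def vector_potential_A(coil: CoilModel, points: np.ndarray) -> FieldSamples:
    """Magnetic vector potential (T·m, Coulomb gauge) at the given points."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    starts, ends, currents = _gather_segments(coil)
    values = _segment_fields(points, starts, ends, currents, want_B=False, coil=coil)
    return FieldSamples(points=points, values=values, kind="A")


def _circle(radius: float, z: float, n_seg: int, phase: float = 0.0) -> np.ndarray:
    t = phase + 2 * np.pi * np.arange(n_seg) / n_seg
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), np.full(n_seg, z)])


def _arc(radius: float, z: float, phi0: float, phi1: float, n_seg: int) -> np.ndarray:
    t = np.linspace(phi0, phi1, n_seg + 1)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), np.full(n_seg + 1, z)])


def _saddle_loop(radius, z_in, z_out, phi_c, half_angle, current, n_seg):
    """Closed saddle: arc at z_in, axial rung, reversed arc at z_out, rung back.

    The azimuthal sense through the inner arc is set by the sign of
    ``current`` (positive = counterclockwise seen from +z).
    """
    a1 = _arc(radius, z_in, phi_c - half_angle, phi_c + half_angle, n_seg)
    a2 = _arc(radius, z_out, phi_c + half_angle, phi_c - half_angle, n_seg)
    return Loop(vertices=np.vstack([a1, a2]), current=current)


def _maxwell_pair_loops(radius: float, turns: float, n_seg: int) -> tuple[list[Loop], float]:
    d = np.sqrt(3) / 2 * radius  # anti-Helmholtz spacing, cancels z^3 term
    loops = [
        Loop(_circle(radius, +d, n_seg), +turns),
        Loop(_circle(radius, -d, n_seg), -turns),
    ]
    return loops, d


def maxwell_pair_efficiency(radius: float, half_spacing: float, current: float = 1.0) -> float:
    """Closed-form on-axis dBz/dz at isocenter of an opposed circular pair."""
    return 3 * MU0 * current * radius**2 * half_spacing / (radius**2 + half_spacing**2) ** 2.5


def _golay_loops(radius, length, axis, turns, n_seg):
    # Classic double-saddle layout: 120 deg arcs; inner arcs near 0.39R,
    # outer arcs clamped to the coil half-length.
    z1 = 0.39 * radius
    z2 = min(2.57 * radius, 0.5 * length)
    half_angle = np.pi / 3
    phi0 = 0.0 if axis == "X" else np.pi / 2  # Y coil = X coil rotated 90 deg
    loops = []
    # Bz = G x is even under z-reflection, so the two saddles on each side
    # carry the same azimuthal sense; the opposite side is reversed.
    for phi_c, side_sign in ((phi0, +1), (phi0 + np.pi, -1)):
        for z_sign in (+1, -1):
            loops.append(
                _saddle_loop(
                    radius,
                    z_sign * z1,
                    z_sign * z2,
                    phi_c,
                    half_angle,
                    turns * side_sign,
                    n_seg,
                )
            )
    return loops


def make_axis_coil(
    axis: str,
    inner_diameter: float = 0.70,
    length: float = 1.40,
    shielded: bool = False,
    turns: float = 1.0,
    n_segments: int = 120,
    shield_radius_factor: float = 1.3,
    allow_unrealistic: bool = False,
) -> CoilModel:
    """Idealized per-axis gradient coil.

    Z uses a Maxwell (anti-Helmholtz) pair; X/Y use a four-saddle Golay
    set, with the Y coil equal to the X coil rotated 90 degrees about z.
    ``shielded`` adds concentric windings at ``shield_radius_factor`` times
    the primary radius with opposing current scaled to cancel the leading
    far-field moment.
    """
    axis = axis.upper()
    if axis not in ("X", "Y", "Z"):
        raise ValueError("axis must be X, Y or Z")
    if not allow_unrealistic:
        if not (REALISTIC_ID_RANGE[0] <= inner_diameter <= REALISTIC_ID_RANGE[1]):
            raise ValueError(
                f"inner diameter {inner_diameter} m outside realistic range "
                f"{REALISTIC_ID_RANGE}; pass allow_unrealistic=True to override"
            )
        if not (REALISTIC_LENGTH_RANGE[0] <= length <= REALISTIC_LENGTH_RANGE[1]):
            raise ValueError(
                f"length {length} m outside realistic range "
                f"{REALISTIC_LENGTH_RANGE}; pass allow_unrealistic=True to override"
            )
    if n_segments < 72:
        raise ValueError("loops must be discretized at >= 72 segments per turn")
    radius = inner_diameter / 2
    if axis == "Z":
        loops, d = _maxwell_pair_loops(radius, turns, n_segments)
        if shielded:
            rs = radius * shield_radius_factor
            if rs <= radius:
                raise ValueError("shield radius must exceed primary radius")
            ds = np.sqrt(3) / 2 * rs
            # Cancel the leading (I R^2 d) moment of the pair.
            i_shield = -turns * (radius**2 * d) / (rs**2 * ds)
            loops += [
                Loop(_circle(rs, +ds, n_segments), +i_shield),
                Loop(_circle(rs, -ds, n_segments), -i_shield),
            ]
    else:
        loops = _golay_loops(radius, length, axis, turns, n_segments // 2)
        if shielded:
            rs = radius * shield_radius_factor
            if rs <= radius:
                raise ValueError("shield radius must exceed primary radius")
            i_shield = -turns * (radius / rs) ** 2
            loops += _golay_loops(rs, length * shield_radius_factor, axis, i_shield, n_segments // 2)
    name = f"{'shielded_' if shielded else ''}{axis.lower()}_id{inner_diameter:.2f}_len{length:.2f}"
    return CoilModel(loops=loops, axis=axis, inner_diameter=inner_diameter, length=length, name=name)


def gradient_efficiency(source, step: float = 1e-3) -> float:
    """Gradient of Bz along the coil's axis at isocenter, per unit drive.

    Central finite difference with 1 mm step. For ideal field objects the
    construction value is returned exactly.
    """
    if isinstance(source, IdealUniformGradient):
        return source.gradient
    if isinstance(source, IdealUniformB):
        raise ValueError("a uniform-B source has no gradient efficiency")
    k = {"X": 0, "Y": 1, "Z": 2}[source.axis]
    pts = np.zeros((2, 3))
    pts[0, k] = -step
    pts[1, k] = +step
    bz = biot_savart_B(source, pts).values[:, 2]
    g = (bz[1] - bz[0]) / (2 * step)
    if abs(g) < 1e-12:
        raise ValueError(f"degenerate coil: |G_eff| = {abs(g):.3e} < 1e-12 T/m")
    return float(g)


@dataclass(frozen=True)
class IdealUniformB:
    """Uniform axial field Bz = B0 with exact A = (B0/2)(-y, x, 0).

    ``rate`` is the dB/dt amplitude (T/s) used when this source drives the
    solver or the compliance metric directly.
    """

    b0: float = 1.0
    rate: float = 100.0

    def A(self, points: np.ndarray) -> FieldSamples:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        vals = 0.5 * self.b0 * np.column_stack(
            [-points[:, 1], points[:, 0], np.zeros(len(points))]
        )
        return FieldSamples(points=points, values=vals, kind="A")

    def B(self, points: np.ndarray) -> FieldSamples:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        vals = np.zeros_like(points)
        vals[:, 2] = self.b0
        return FieldSamples(points=points, values=vals, kind="B")

    def dAdt(self, points: np.ndarray) -> FieldSamples:
        a = self.A(points)
        return FieldSamples(points=a.points, values=a.values * (self.rate / self.b0), kind="dAdt")


@dataclass(frozen=True)
class IdealUniformGradient:
    """Idealized longitudinal gradient Bz = G z.

    ``B`` returns the axial component (0, 0, G z) only — the idealization
    used for compliance-volume oracles. ``A`` is the gauge
    A = (G/2)(-yz, xz, 0), whose curl G(-x/2, -y/2, z) carries the
    transverse terms required by div B = 0; the solver consumes A.
    """

    gradient: float = 1.0  # T/m per unit drive

    @property
    def axis(self) -> str:
        return "Z"

    def A(self, points: np.ndarray) -> FieldSamples:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        g = self.gradient
        vals = 0.5 * g * np.column_stack(
            [-points[:, 1] * points[:, 2], points[:, 0] * points[:, 2], np.zeros(len(points))]
        )
        return FieldSamples(points=points, values=vals, kind="A")

    def B(self, points: np.ndarray) -> FieldSamples:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        vals = np.zeros_like(points)
        vals[:, 2] = self.gradient * points[:, 2]
        return FieldSamples(points=points, values=vals, kind="B")


def make_ideal_field(kind: str, magnitude: float, rate: float = 100.0):
    """Synthetic field source bypassing Biot-Savart in validation scenarios."""
    if not np.isfinite(magnitude):
        raise ValueError("magnitude must be finite")
    if kind == "uniform_B":
        return IdealUniformB(b0=magnitude, rate=rate)
    if kind == "uniform_gradient":
        return IdealUniformGradient(gradient=magnitude)
    raise ValueError(f"unknown ideal field kind {kind!r}")


def _source_B(source, points: np.ndarray) -> np.ndarray:
    if isinstance(source, (IdealUniformB, IdealUniformGradient)):
        return source.B(points).values
    return biot_savart_B(source, points).values


def compliance_peak_dBdt(source, drive: DriveSpec, cv: ComplianceVolume) -> float:
    """Peak dB/dt (T/s) over the compliance cylinder at the drive's slew.

    Peak |B| per unit current over the sample grid, scaled by
    slew / G_eff. A uniform-B ideal source returns its dB/dt rate
    directly (|B| is constant). For axis combinations, pass a list of
    per-axis sources; each is driven at slew/sqrt(n) in phase and the
    fields are summed vectorially before |B| is taken.
    """
    pts = cv.sample_points()
    sources = source if isinstance(source, (list, tuple)) else [source]
    total = np.zeros((len(pts), 3))
    for src in sources:
        if isinstance(src, IdealUniformB):
            if len(sources) > 1:
                raise ValueError("uniform-B source cannot be combined with other axes")
            return float(src.rate)
        g_eff = gradient_efficiency(src)
        slew = drive.slew / np.sqrt(len(sources))
        total += _source_B(src, pts) * (slew / g_eff)
    return float(np.max(np.linalg.norm(total, axis=1)))
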
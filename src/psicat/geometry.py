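"""Kanizsa subjective-contour stimulus geometry.

Targets are irregular convex polygons whose vertices carry 'Pac-Man'
inducers: discs with a wedge (mouth) removed, the mouth angle equalling the
polygon's interior angle at that vertex.  When every mouth's edges are
collinear with the polygon edges the array induces a subjective contour
illusion (SCI); rotating each inducer by an independent random offset
destroys collinearity (no-SCI) while leaving every low-level feature —
inducer centres, radii, mouth angles, hence total ink area — identical.

Primers are thin line angle-figures shown briefly before the target: one
two-segment angle per vertex.  A congruent primer traces the target's own
mouth edges; an incongruent primer traces the mouth edges of the
opposite-class twin built from the same polygon, so it reinforces the
opposite stimulus class.

All coordinates are degrees of visual angle, centre origin, y-up.
Generation is a pure function of (config, seed): identical inputs produce
bit-identical stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConfigurationError",
    "GeometryConfig",
    "PolygonSpec",
    "InducerSpec",
    "TargetStimulus",
    "PrimerStimulus",
    "Segment",
    "generate_polygon",
    "make_target",
    "make_primer",
    "make_stimulus_pair",
    "mouth_edge_directions",
    "measured_rotation_offsets",
    "ink_area",
]


class ConfigurationError(ValueError):
    """Raised when a geometry configuration is infeasible or inconsistent."""


def _wrap_deg(a):
    """Wrap angle(s) to (-180, 180]."""
    return -((180.0 - np.asarray(a)) % 360.0 - 180.0)


@dataclass(frozen=True)
class GeometryConfig:
    """Constraints on stimulus construction, in degrees of visual angle.

    ``interior_angle_bounds`` maps vertex count to the admissible interior
    angle range; defaults keep the Pac-Men non-overlapping and the mouths
    drawable for both triangles and quadrilaterals.
    """

    canvas_size: float = 10.0
    circumradius_mean: float = 3.0
    circumradius_jitter: float = 0.5
    angular_jitter: float = 20.0
    inducer_radius: float = 1.0
    interior_angle_bounds: dict = field(
        default_factory=lambda: {3: (30.0, 120.0), 4: (50.0, 130.0)}
    )
    nosci_rotation_bounds: tuple = (40.0, 140.0)
    primer_segment_length: float = 1.0
    target_color: str = "white"
    primer_color: str = "red"
    background_color: str = "black"
    primer_line_width: float = 0.06  # degrees
    max_retries: int = 1000

    def validate(self) -> "GeometryConfig":
        for n, (lo, hi) in self.interior_angle_bounds.items():
            if not (0.0 < lo < hi < 180.0):
                raise ConfigurationError(
                    f"interior angle bounds for n={n} must satisfy 0 < min < max < 180"
                )
        lo, hi = self.nosci_rotation_bounds
        if not (0.0 < lo <= hi):
            raise ConfigurationError("no-SCI rotation bounds must be positive")
        if self.circumradius_mean <= self.circumradius_jitter:
            raise ConfigurationError("circumradius jitter exceeds its mean")
        # inducers must stay clear of each other: the tightest case is two
        # vertices at minimum radius separated by the minimum angular gap
        n_max = max(self.interior_angle_bounds)
        min_gap = 360.0 / n_max - 2.0 * self.angular_jitter
        if min_gap <= 0:
            raise ConfigurationError("angular jitter allows coincident vertices")
        r_min = self.circumradius_mean - self.circumradius_jitter
        min_dist = 2.0 * r_min * np.sin(np.radians(min_gap / 2.0))
        if self.inducer_radius >= min_dist / 2.0:
            raise ConfigurationError(
                "inducer radius too large: Pac-Men may overlap "
                f"(radius {self.inducer_radius} >= {min_dist / 2.0:.3f})"
            )
        return self


@dataclass(frozen=True)
class PolygonSpec:
    n_vertices: int
    vertices: tuple  # ((x, y), ...) degrees, centre origin
    interior_angles: tuple  # degrees, one per vertex

    def vertex_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)


@dataclass(frozen=True)
class InducerSpec:
    center: tuple
    radius: float
    mouth_angle: float  # degrees; equals the interior angle at this vertex
    mouth_orientation: float  # realized mouth-bisector direction, degrees
    rotation_offset: float  # 0 for SCI; signed offset from collinear for no-SCI


@dataclass(frozen=True)
class TargetStimulus:
    stimulus_id: str
    target_class: str  # "SCI" | "noSCI"
    polygon: PolygonSpec
    inducers: tuple


@dataclass(frozen=True)
class Segment:
    vertex_index: int
    start: tuple
    end: tuple


@dataclass(frozen=True)
class PrimerStimulus:
    primer_id: str
    congruency: str  # "con" | "inc"
    segments: tuple  # 2 per vertex, sharing the vertex endpoint
    source_target_id: str


# ---------------------------------------------------------------------------
# polygon sampling

def _interior_angles(verts: np.ndarray) -> np.ndarray:
    n = len(verts)
    ang = np.empty(n)
    for i in range(n):
        u = verts[(i - 1) % n] - verts[i]
        v = verts[(i + 1) % n] - verts[i]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        ang[i] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return ang


def _cross2(u: np.ndarray, v: np.ndarray) -> float:
    return float(u[0] * v[1] - u[1] * v[0])


def _is_convex(verts: np.ndarray) -> bool:
    n = len(verts)
    cross = [
        _cross2(verts[(i + 1) % n] - verts[i], verts[(i + 2) % n] - verts[(i + 1) % n])
        for i in range(n)
    ]
    return all(c > 0 for c in cross) or all(c < 0 for c in cross)


def generate_polygon(n_vertices: int, config: GeometryConfig, rng: np.random.Generator) -> PolygonSpec:
    """Sample an irregular convex polygon satisfying the angle constraints.

    Vertices sit at jittered angular positions on a jittered-radius circle;
    candidates violating the interior-angle bounds (or convexity) are
    rejected and resampled, up to ``config.max_retries`` attempts.
    """
    if n_vertices not in (3, 4):
        raise ConfigurationError("n_vertices must be 3 or 4")
    config.validate()
    try:
        lo, hi = config.interior_angle_bounds[n_vertices]
    except KeyError:
        raise ConfigurationError(f"no interior-angle bounds for n={n_vertices}")
    total = (n_vertices - 2) * 180.0
    if n_vertices * lo > total or n_vertices * hi < total:
        raise ConfigurationError(
            f"interior-angle bounds [{lo}, {hi}] infeasible for n={n_vertices}: "
            f"angles must sum to {total}"
        )
    base = 90.0 + np.arange(n_vertices) * 360.0 / n_vertices
    for _ in range(config.max_retries):
        theta = base + rng.uniform(-config.angular_jitter, config.angular_jitter, n_vertices)
        radii = rng.uniform(
            config.circumradius_mean - config.circumradius_jitter,
            config.circumradius_mean + config.circumradius_jitter,
            n_vertices,
        )
        verts = np.column_stack(
            [radii * np.cos(np.radians(theta)), radii * np.sin(np.radians(theta))]
        )
        if not _is_convex(verts):
            continue
        ang = _interior_angles(verts)
        if np.all(ang >= lo) and np.all(ang <= hi):
            return PolygonSpec(
                n_vertices=n_vertices,
                vertices=tuple(map(tuple, verts)),
                interior_angles=tuple(ang),
            )
    raise ConfigurationError(
        f"could not sample an n={n_vertices} polygon within "
        f"{config.max_retries} retries; bounds too tight"
    )


# ---------------------------------------------------------------------------
# targets

def _mouth_bisectors(polygon: PolygonSpec) -> np.ndarray:
    """Collinear mouth-bisector direction (deg) at each vertex.

    The bisector of the two polygon edges leaving the vertex: with the mouth
    symmetric about it, the mouth edges coincide with the polygon edges.
    """
    verts = polygon.vertex_array()
    n = len(verts)
    out = np.empty(n)
    for i in range(n):
        u = verts[(i - 1) % n] - verts[i]
        v = verts[(i + 1) % n] - verts[i]
        b = u / np.linalg.norm(u) + v / np.linalg.norm(v)
        out[i] = np.degrees(np.arctan2(b[1], b[0]))
    return out


def make_target(
    polygon: PolygonSpec,
    cls: str,
    config: GeometryConfig,
    rng: np.random.Generator,
    stimulus_id: str = "",
) -> TargetStimulus:
    """Attach one Pac-Man inducer per vertex, collinear (SCI) or rotated (no-SCI).

    For no-SCI each inducer is independently rotated by a magnitude drawn
    uniformly from ``config.nosci_rotation_bounds`` with random sign.
    Inducer centres, radii and mouth angles are identical across classes for
    the same polygon, so low-level features are matched.
    """
    if cls not in ("SCI", "noSCI"):
        raise ConfigurationError(f"target class must be 'SCI' or 'noSCI', got {cls!r}")
    bis = _mouth_bisectors(polygon)
    n = polygon.n_vertices
    if cls == "SCI":
        offsets = np.zeros(n)
    else:
        lo, hi = config.nosci_rotation_bounds
        offsets = rng.uniform(lo, hi, n) * rng.choice([-1.0, 1.0], n)
    inducers = tuple(
        InducerSpec(
            center=polygon.vertices[i],
            radius=config.inducer_radius,
            mouth_angle=polygon.interior_angles[i],
            mouth_orientation=float(_wrap_deg(bis[i] + offsets[i])),
            rotation_offset=float(offsets[i]),
        )
        for i in range(n)
    )
    return TargetStimulus(
        stimulus_id=stimulus_id or f"tgt-{cls}-{n}v",
        target_class=cls,
        polygon=polygon,
        inducers=inducers,
    )


def mouth_edge_directions(ind: InducerSpec) -> tuple:
    """Directions (deg) of the two mouth edges, from the vertex outward."""
    half = ind.mouth_angle / 2.0
    return (
        float(_wrap_deg(ind.mouth_orientation - half)),
        float(_wrap_deg(ind.mouth_orientation + half)),
    )


def measured_rotation_offsets(target: TargetStimulus) -> np.ndarray:
    """Re-measure each inducer's offset from collinear, from emitted geometry."""
    bis = _mouth_bisectors(target.polygon)
    meas = [_wrap_deg(ind.mouth_orientation - bis[i]) for i, ind in enumerate(target.inducers)]
    return np.asarray(meas, dtype=float)


def ink_area(target: TargetStimulus) -> float:
    """Exact vector ink area of all inducers (square degrees)."""
    return float(
        sum(np.pi * ind.radius**2 * (1.0 - ind.mouth_angle / 360.0) for ind in target.inducers)
    )


# ---------------------------------------------------------------------------
# primers

def make_primer(
    target: TargetStimulus,
    congruency: str,
    config: GeometryConfig,
    rng: np.random.Generator,
    primer_id: str = "",
) -> PrimerStimulus:
    """Build the line angle-figure primer for a target.

    Congruent primers trace the target's own mouth edges; incongruent
    primers trace the mouth edges of the opposite-class target built from
    the same polygon, so their per-vertex orientations differ from the
    target's by at least the configured no-SCI rotation minimum.
    """
    if congruency not in ("con", "inc"):
        raise ConfigurationError(f"congruency must be 'con' or 'inc', got {congruency!r}")
    if congruency == "con":
        source = target
    else:
        other = "noSCI" if target.target_class == "SCI" else "SCI"
        source = make_target(target.polygon, other, config, rng)
    length = config.primer_segment_length
    segments = []
    for i, ind in enumerate(source.inducers):
        vx, vy = ind.center
        for d in mouth_edge_directions(ind):
            rad = np.radians(d)
            segments.append(
                Segment(
                    vertex_index=i,
                    start=(vx, vy),
                    end=(vx + length * np.cos(rad), vy + length * np.sin(rad)),
                )
            )
    return PrimerStimulus(
        primer_id=primer_id or f"pri-{congruency}-{target.stimulus_id}",
        congruency=congruency,
        segments=tuple(segments),
        source_target_id=target.stimulus_id,
    )


def make_stimulus_pair(
    n_vertices: int,
    target_class: str,
    congruency: str,
    config: GeometryConfig,
    rng: np.random.Generator,
    stimulus_id: str = "",
):
    """Convenience: fresh polygon -> (target, primer) for one trial."""
    poly = generate_polygon(n_vertices, config, rng)
    target = make_target(poly, target_class, config, rng, stimulus_id=stimulus_id)
    primer = make_primer(target, congruency, config, rng)
    return target, primer
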
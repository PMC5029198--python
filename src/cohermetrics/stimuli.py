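"""Coherence-defined global motion and global form stimuli.

Four stimulus classes are generated as abstract geometric frame sequences,
all parameterised by a coherence percentage (the fraction of elements
carrying the global signal):

* random-dot kinematogram (RDK) global motion — 200 dots, signal dots
  translate up or down, noise dots take constant-speed steps in random
  directions, signal/noise assignment re-randomised on every update;
* spatially one-dimensional global motion — 50 full-width horizontal bars
  whose only degree of freedom is vertical position; noise bars move up or
  down with equal probability at the same speed as signal bars;
* static global form — an 8-frame dot sequence with *fixed* signal/noise
  assignment, spatially superimposed into a single image so that signal
  dots leave collinear streaks along a common axis;
* temporally-defined global form — 200 static dots split into two
  populations of 100 that are jittered on alternating updates; a boundary
  becomes visible only through the spatial segregation of jitter timing.

Coordinates are in degrees of visual angle inside a 12 deg x 12 deg window.
Elements update at 18.75 Hz (every 4th frame of a 75 Hz display); each
update displaces a moving element by 0.12 deg, and an 8-image sequence
lasts 8 / 18.75 ~= 0.43 s.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DisplayGeometry",
    "ElementSpec",
    "CoherenceSpec",
    "FrameSequence",
    "StaticFormImage",
    "generate_rdk_sequence",
    "generate_bar_sequence",
    "collapse_to_static_form",
    "generate_temporal_form_sequence",
    "empirical_coherence",
    "signal_count",
    "write_frames",
    "read_frames",
]

TASK_KINDS = ("rdk_motion", "bar_motion", "static_form", "temporal_form")
MOTION_TASKS = ("rdk_motion", "bar_motion")

#: unit displacement vectors for the two global-motion alternatives
DIRECTION_VECTORS = {"up": np.array([0.0, 1.0]), "down": np.array([0.0, -1.0])}
#: unit axis vectors for the two global-form alternatives
AXIS_VECTORS = {"vertical": np.array([0.0, 1.0]), "horizontal": np.array([1.0, 0.0])}


@dataclass(frozen=True)
class DisplayGeometry:
    """Abstract display geometry (degrees of visual angle, cd/m2, Hz)."""

    window_width_deg: float = 12.0
    window_height_deg: float = 12.0
    element_luminance_cd_m2: float = 0.01
    background_luminance_cd_m2: float = 34.0
    viewing_distance_cm: float = 114.0
    refresh_hz: float = 75.0
    update_hz: float = 18.75

    def __post_init__(self) -> None:
        for name in ("window_width_deg", "window_height_deg", "viewing_distance_cm",
                     "refresh_hz", "update_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        ratio = self.refresh_hz / self.update_hz
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("update_hz must divide refresh_hz evenly")

    @property
    def frames_per_update(self) -> int:
        return round(self.refresh_hz / self.update_hz)


@dataclass(frozen=True)
class ElementSpec:
    """Elements populating the window: small dots or full-width bars."""

    kind: str = "dot"  # {"dot", "bar"}
    count: int = 200
    dot_diameter_deg: float = 0.12
    bar_length_deg: float = 12.0  # bar width equals the dot diameter

    def __post_init__(self) -> None:
        if self.kind not in ("dot", "bar"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.count <= 0:
            raise ValueError("element count must be positive")

    @classmethod
    def dots(cls, count: int = 200) -> "ElementSpec":
        return cls(kind="dot", count=count)

    @classmethod
    def bars(cls, count: int = 50) -> "ElementSpec":
        return cls(kind="bar", count=count)


@dataclass(frozen=True)
class CoherenceSpec:
    """Coherence level and signal identity for one stimulus presentation.

    ``signal_direction`` is "up"/"down" for the motion tasks and
    "vertical"/"horizontal" for the form tasks (streak axis, or boundary
    orientation for the temporally-defined task).
    """

    coherence_pct: float
    signal_direction: str = "up"
    displacement_deg: float = 0.12
    n_images: int = 8

    def __post_init__(self) -> None:
        if not 0.0 <= self.coherence_pct <= 100.0:
            raise ValueError("coherence_pct must lie in [0, 100]")
        if self.displacement_deg <= 0:
            raise ValueError("displacement_deg must be positive")
        if self.n_images < 2:
            raise ValueError("need at least two images")
        if self.signal_direction not in (*DIRECTION_VECTORS, *AXIS_VECTORS):
            raise ValueError(f"unknown signal_direction {self.signal_direction!r}")


def signal_count(coherence_pct: float, n_elements: int) -> int:
    """Number of signal elements: coherence is quantised to whole elements."""
    if not 0.0 <= coherence_pct <= 100.0:
        raise ValueError("coherence_pct must lie in [0, 100]")
    return int(np.rint(coherence_pct / 100.0 * n_elements))


@dataclass
class FrameSequence:
    """Ordered per-element positions for one stimulus presentation.

    ``frames`` has shape (n_images, n_elements, 2) holding (x, y) in
    degrees; ``element_roles`` has shape (n_images - 1, n_elements) and
    marks, for each inter-frame update, which elements carried the signal
    (motion tasks) or were jittered (temporal-form task).
    """

    frames: np.ndarray
    element_roles: np.ndarray
    task_kind: str
    signal_direction: str
    displacement_deg: float
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)
    populations: np.ndarray | None = None  # temporal-form: 1 or 2 per dot

    def __post_init__(self) -> None:
        if self.task_kind not in TASK_KINDS:
            raise ValueError(f"unknown task kind {self.task_kind!r}")
        if self.frames.ndim != 3 or self.frames.shape[2] != 2:
            raise ValueError("frames must have shape (n_images, n_elements, 2)")
        if self.element_roles.shape != (self.n_frames - 1, self.n_elements):
            raise ValueError("element_roles must have shape (n_images - 1, n_elements)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_elements(self) -> int:
        return self.frames.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.geometry.update_hz

    def displacements(self) -> np.ndarray:
        """Per-update displacement vectors, unwrapped across the toroidal edge."""
        d = np.diff(self.frames, axis=0)
        span = np.array([self.geometry.window_width_deg, self.geometry.window_height_deg])
        return (d + span / 2.0) % span - span / 2.0

    def to_table(self) -> pd.DataFrame:
        """Long-format table: one row per element per frame.

        ``role`` flags signal membership for the update *starting* at that
        frame; it is empty for the final frame.
        """
        f, n = self.n_frames, self.n_elements
        roles = np.full((f, n), "", dtype=object)
        roles[:-1][self.element_roles] = "signal"
        roles[:-1][~self.element_roles] = "noise"
        return pd.DataFrame({
            "frame": np.repeat(np.arange(f), n),
            "element": np.tile(np.arange(n), f),
            "x_deg": self.frames[:, :, 0].ravel(),
            "y_deg": self.frames[:, :, 1].ravel(),
            "role": roles.ravel(),
        })


@dataclass
class StaticFormImage:
    """Superposition of an 8-frame sequence into one static image.

    ``trails`` keeps the (n_images, n_dots, 2) positions so that the
    constituent per-dot trails remain identifiable; ``dot_positions``
    flattens them into the single image the observer would see.
    """

    trails: np.ndarray
    signal_axis: str
    signal_mask: np.ndarray  # (n_dots,) fixed signal/noise assignment
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)

    @property
    def n_dots(self) -> int:
        return self.trails.shape[1]

    @property
    def dot_positions(self) -> np.ndarray:
        return self.trails.reshape(-1, 2)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _initial_positions(geometry: DisplayGeometry, n: int, rng: np.random.Generator) -> np.ndarray:
    w, h = geometry.window_width_deg, geometry.window_height_deg
    return rng.uniform([0.0, 0.0], [w, h], size=(n, 2))


def _wrap(pos: np.ndarray, geometry: DisplayGeometry) -> np.ndarray:
    span = np.array([geometry.window_width_deg, geometry.window_height_deg])
    return pos % span


def generate_rdk_sequence(geometry: DisplayGeometry, elements: ElementSpec,
                          spec: CoherenceSpec, seed) -> FrameSequence:
    """Random-dot kinematogram: signal dots translate coherently, noise dots
    take equal-length steps in uniformly random directions, and the
    signal/noise assignment is re-drawn on every update."""
    if elements.kind != "dot":
        raise ValueError("RDK stimuli require dot elements")
    if spec.signal_direction not in DIRECTION_VECTORS:
        raise ValueError("motion tasks need signal_direction 'up' or 'down'")
    rng = _as_rng(seed)
    n, k = elements.count, signal_count(spec.coherence_pct, elements.count)
    step = spec.displacement_deg * DIRECTION_VECTORS[spec.signal_direction]

    frames = np.empty((spec.n_images, n, 2))
    roles = np.zeros((spec.n_images - 1, n), dtype=bool)
    frames[0] = _initial_positions(geometry, n, rng)
    for u in range(spec.n_images - 1):
        sig = rng.permutation(n)[:k]
        roles[u, sig] = True
        disp = np.empty((n, 2))
        disp[roles[u]] = step
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n - k)
        disp[~roles[u]] = spec.displacement_deg * np.column_stack(
            [np.cos(theta), np.sin(theta)])
        frames[u + 1] = _wrap(frames[u] + disp, geometry)
    return FrameSequence(frames, roles, "rdk_motion", spec.signal_direction,
                         spec.displacement_deg, geometry)


def generate_bar_sequence(geometry: DisplayGeometry, elements: ElementSpec,
                          spec: CoherenceSpec, seed) -> FrameSequence:
    """Spatially 1-D analogue of the RDK: full-width horizontal bars moving
    only vertically; noise bars pick up/down with probability one half, so
    every bar moves at the same speed on every update."""
    if elements.kind != "bar":
        raise ValueError("1-D motion stimuli require bar elements")
    if spec.signal_direction not in DIRECTION_VECTORS:
        raise ValueError("motion tasks need signal_direction 'up' or 'down'")
    rng = _as_rng(seed)
    n, k = elements.count, signal_count(spec.coherence_pct, elements.count)
    sgn = 1.0 if spec.signal_direction == "up" else -1.0

    frames = np.empty((spec.n_images, n, 2))
    roles = np.zeros((spec.n_images - 1, n), dtype=bool)
    x = np.full(n, geometry.window_width_deg / 2.0)  # bars span the window
    frames[0] = np.column_stack([x, rng.uniform(0.0, geometry.window_height_deg, n)])
    for u in range(spec.n_images - 1):
        sig = rng.permutation(n)[:k]
        roles[u, sig] = True
        dy = np.where(roles[u], sgn, rng.integers(0, 2, size=n) * 2.0 - 1.0)
        frames[u + 1] = frames[u].copy()
        frames[u + 1, :, 1] = (frames[u, :, 1] + dy * spec.displacement_deg) \
            % geometry.window_height_deg
    return FrameSequence(frames, roles, "bar_motion", spec.signal_direction,
                         spec.displacement_deg, geometry)


def collapse_to_static_form(geometry: DisplayGeometry, elements: ElementSpec,
                            spec: CoherenceSpec, seed) -> StaticFormImage:
    """Static global form: build an 8-frame dot sequence with signal/noise
    assignment *fixed* for the whole sequence, then superimpose the frames.

    Each signal dot steps in a fixed direction (randomly + or -) along the
    common axis, leaving a collinear streak of extent
    (n_images - 1) * displacement; noise dots random-walk.  Positions are
    deliberately not wrapped: a toroidal wrap would cut streaks near the
    window edge in two, destroying the oriented structure the task is
    defined by.
    """
    if elements.kind != "dot":
        raise ValueError("static form stimuli require dot elements")
    if spec.signal_direction not in AXIS_VECTORS:
        raise ValueError("form tasks need signal_direction 'vertical' or 'horizontal'")
    rng = _as_rng(seed)
    n, k = elements.count, signal_count(spec.coherence_pct, elements.count)
    axis = AXIS_VECTORS[spec.signal_direction]

    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:k]] = True
    sign = rng.integers(0, 2, size=n) * 2.0 - 1.0  # fixed per-dot streak direction

    trails = np.empty((spec.n_images, n, 2))
    trails[0] = _initial_positions(geometry, n, rng)
    for u in range(spec.n_images - 1):
        disp = np.empty((n, 2))
        disp[mask] = np.outer(sign[mask], axis) * spec.displacement_deg
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n - int(mask.sum()))
        disp[~mask] = spec.displacement_deg * np.column_stack(
            [np.cos(theta), np.sin(theta)])
        trails[u + 1] = trails[u] + disp
    return StaticFormImage(trails, spec.signal_direction, mask, geometry)


def generate_temporal_form_sequence(geometry: DisplayGeometry, elements: ElementSpec,
                                    spec: CoherenceSpec, seed) -> FrameSequence:
    """Temporally-defined global form.

    The dots are split into two populations of equal size that are jittered
    (one displacement-length step in a random direction) on strictly
    alternating updates — on every update exactly half the dots move and
    half stay put.  A fraction C/100 of the dots have their population
    membership dictated by their side of the midline boundary; the rest are
    assigned at random subject to the equal split.  Dots are placed
    uniformly but balanced, with exactly half on each side of the candidate
    boundary, so the equal split and a fully coherent boundary can coexist.
    """
    if elements.kind != "dot":
        raise ValueError("temporal form stimuli require dot elements")
    if spec.signal_direction not in AXIS_VECTORS:
        raise ValueError("form tasks need signal_direction 'vertical' or 'horizontal'")
    if elements.count % 2:
        raise ValueError("temporal form task needs an even element count")
    rng = _as_rng(seed)
    n, k = elements.count, signal_count(spec.coherence_pct, elements.count)
    half = n // 2

    if n % 4:
        raise ValueError("temporal form task needs an element count divisible by four")
    w, h = geometry.window_width_deg, geometry.window_height_deg
    # quadrant-stratified placement: both the left/right and bottom/top
    # splits hold exactly half the dots, so the boundary is carried by the
    # jitter timing alone and never by a density imbalance on either axis
    q = n // 4
    quad = np.repeat(np.arange(4), q)
    pos = rng.uniform([0.0, 0.0], [w / 2.0, h / 2.0], size=(n, 2))
    pos[:, 0] += np.where(quad % 2 == 1, w / 2.0, 0.0)
    pos[:, 1] += np.where(quad >= 2, h / 2.0, 0.0)
    pos = pos[rng.permutation(n)]
    if spec.signal_direction == "vertical":
        side_a = pos[:, 0] < w / 2.0
    else:
        side_a = pos[:, 1] < h / 2.0

    coherent = np.zeros(n, dtype=bool)
    coherent[rng.permutation(n)[:k]] = True
    population = np.zeros(n, dtype=int)
    population[coherent & side_a] = 1
    population[coherent & ~side_a] = 2
    free = np.flatnonzero(population == 0)
    need1 = half - int((population == 1).sum())
    fill = rng.permutation(free)
    population[fill[:need1]] = 1
    population[fill[need1:]] = 2

    frames = np.empty((spec.n_images, n, 2))
    roles = np.zeros((spec.n_images - 1, n), dtype=bool)
    frames[0] = pos
    for u in range(spec.n_images - 1):
        moving = population == (1 if u % 2 == 0 else 2)
        roles[u] = moving
        disp = np.zeros((n, 2))
        theta = rng.uniform(0.0, 2.0 * np.pi, size=int(moving.sum()))
        disp[moving] = spec.displacement_deg * np.column_stack(
            [np.cos(theta), np.sin(theta)])
        frames[u + 1] = _wrap(frames[u] + disp, geometry)
    return FrameSequence(frames, roles, "temporal_form", spec.signal_direction,
                         spec.displacement_deg, geometry, populations=population)


def empirical_coherence(seq: FrameSequence) -> float:
    """Percentage of element displacements exactly matching the signal vector.

    For a motion sequence at coherence C this is at least C, because noise
    elements occasionally move in the signal direction by chance (always a
    possibility for bars, whose noise has only two directions).
    """
    if seq.task_kind not in MOTION_TASKS:
        raise ValueError(f"empirical_coherence requires a motion task, got {seq.task_kind!r}")
    target = seq.displacement_deg * DIRECTION_VECTORS[seq.signal_direction]
    match = np.all(np.isclose(seq.displacements(), target, atol=1e-9), axis=2)
    return 100.0 * float(match.mean())


# ---------------------------------------------------------------------------
# delimited-text export / round-trip


def write_frames(seq: FrameSequence, path) -> None:
    """Write a frame sequence as delimited text with a one-line metadata header."""
    header = (f"# task={seq.task_kind} direction={seq.signal_direction} "
              f"displacement={seq.displacement_deg!r}\n")
    buf = io.StringIO()
    seq.to_table().to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(buf.getvalue())


def read_frames(path) -> FrameSequence:
    """Round-trip reader for :func:`write_frames`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing metadata header")
        meta = dict(item.split("=", 1) for item in header[1:].split())
        table = pd.read_csv(fh, keep_default_na=False)
    f = int(table["frame"].max()) + 1
    n = int(table["element"].max()) + 1
    frames = np.column_stack([table["x_deg"], table["y_deg"]]).reshape(f, n, 2)
    roles = (table["role"].to_numpy().reshape(f, n)[:-1] == "signal")
    return FrameSequence(frames, roles, meta["task"], meta["direction"],
                         float(meta["displacement"]))
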
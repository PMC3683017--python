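"""Rendering of hand-object scenes and retinal-shift training sequences.

Each training stimulus is a greyscale scene containing an asymmetric hand
silhouette and a filled circular target object placed at one of ``n``
hand-relative locations evenly spaced on a semicircle above the hand.  A
*sequence* is the same rigid scene translated horizontally in fixed pixel
steps, emulating the retinal slip produced by small eye movements around a
static scene: the hand-relative geometry never changes within a sequence,
only the retinal position.

Conventions: 0-based pixel indices, origin top-left, x rightward, y
downward; "Up" therefore means smaller y than the hand centre.  Background
is 0; the hand and object are drawn at distinct positive grey levels (the
object on top), which keeps the two shapes separable in the rendered image.
The hand is drawn as a thin-stroke line drawing (the outline of a palm,
four fingers and an offset thumb) while the target is a filled disc: this
keeps the oriented-edge energy of the constant hand comparable to that of
the small moving target, so that competitive learning is driven by the
hand-object geometry rather than swamped by the hand alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

HAND_LEVEL = 0.45
OBJECT_LEVEL = 1.0

__all__ = [
    "SceneSpec",
    "SceneSequence",
    "SceneClippedError",
    "target_offset",
    "target_offsets",
    "location_labels",
    "render_scene",
    "make_sequence",
    "build_training_set",
    "default_scene_spec",
    "export_sequences",
]


class SceneClippedError(ValueError):
    """Raised when a requested shift would clip the hand or object."""


@dataclass(frozen=True)
class SceneSpec:
    """Geometry of one hand-object configuration on the retina.

    ``hand_centre`` is the (x, y) position of the palm centre at shift 0.
    Target locations are indexed on a semicircle of ``semicircle_diameter``
    pixels centred on the hand centre, spanning the upper half plane from
    the rightmost point (angle 0) to the leftmost (angle 180 degrees).
    """

    retina_size: int = 128
    hand_centre: tuple[float, float] = (54.0, 64.0)
    n_target_locations: int = 3
    target_location_index: int = 0
    semicircle_diameter: float = 36.0
    object_radius: float = 8.0
    hand_scale: float = 24.0
    hand_stroke: float = 1.5
    hand_level: float = HAND_LEVEL
    object_level: float = OBJECT_LEVEL

    def __post_init__(self) -> None:
        if not (1 <= self.n_target_locations):
            raise ValueError("need at least one target location")
        if not (0 <= self.target_location_index < self.n_target_locations):
            raise ValueError(
                f"target_location_index {self.target_location_index} out of range "
                f"for {self.n_target_locations} locations"
            )


@dataclass
class SceneSequence:
    """Frames of one configuration rigidly translated across the retina."""

    config_label: str
    spec: SceneSpec
    frames: list[np.ndarray]
    shift_step: int
    n_shifts: int
    shifts: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)


def target_offset(spec: SceneSpec) -> tuple[float, float]:
    """Hand-relative (dx, dy) offset of the target-object centre."""
    n = spec.n_target_locations
    i = spec.target_location_index
    if n == 1:
        angle = math.pi / 2.0
    else:
        angle = math.pi * i / (n - 1)
    r = spec.semicircle_diameter / 2.0
    return (r * math.cos(angle), -r * math.sin(angle))


def target_offsets(n_locations: int, semicircle_diameter: float = 36.0) -> list[tuple[float, float]]:
    """Offsets of all ``n_locations`` targets, rightmost (index 0) to leftmost."""
    specs = [
        SceneSpec(n_target_locations=n_locations, target_location_index=i,
                  semicircle_diameter=semicircle_diameter)
        for i in range(n_locations)
    ]
    return [target_offset(s) for s in specs]


def location_labels(n_locations: int) -> list[str]:
    """Human-readable labels; the 3-location case uses Up / Left / Right."""
    if n_locations == 3:
        # geometric indices: 0 = right, 1 = up, 2 = left
        return ["Right", "Up", "Left"]
    return [f"loc{i + 1}" for i in range(n_locations)]


def _hand_primitives(spec: SceneSpec) -> tuple[list, list]:
    """Discs and capsules (segment + width) making up the hand silhouette.

    An open hand seen palm-on: palm disc at the hand centre, four fingers
    of graded lengths extending upward into the band swept by the target
    semicircle, and a thumb angled up-left.  The thumb and the graded
    fingers break mirror symmetry so that 'Left' and 'Right' object
    placements produce pixel-distinct scenes, and targets at neighbouring
    semicircle locations overlap different fingers — giving each
    hand-relative location a distinct local hand-object conjunction.
    """
    cx, cy = spec.hand_centre
    s = spec.hand_scale
    palm_r = 0.40 * s
    discs = [(cx, cy, palm_r)]
    capsules = []
    lengths = (0.80, 0.95, 0.88, 0.68)  # index..little finger
    finger_w = 0.16 * s
    for k in range(4):
        fx = cx + (k - 1.5) * 0.26 * s
        y0 = cy - palm_r * 0.5
        capsules.append(((fx, y0), (fx, y0 - lengths[k] * 0.9 * s), finger_w))
    # thumb: left side, angled outward-up
    t0 = (cx - palm_r * 0.9, cy - 0.05 * s)
    t1 = (cx - palm_r * 0.9 - 0.45 * s, cy - 0.45 * s)
    capsules.append((t0, t1, finger_w * 1.2))
    return discs, capsules


def _scene_bounds(spec: SceneSpec, shift: int) -> tuple[float, float, float, float]:
    """Analytic bounding box (xmin, xmax, ymin, ymax) of all drawn shapes."""
    discs, capsules = _hand_primitives(spec)
    ox, oy = target_offset(spec)
    cx, cy = spec.hand_centre
    discs = discs + [(cx + ox, cy + oy, spec.object_radius)]
    xs, ys = [], []
    for dx, dy, r in discs:
        xs += [dx - r, dx + r]
        ys += [dy - r, dy + r]
    for (x0, y0), (x1, y1), w in capsules:
        half = w / 2.0
        xs += [min(x0, x1) - half, max(x0, x1) + half]
        ys += [min(y0, y1) - half, max(y0, y1) + half]
    return (min(xs) + shift, max(xs) + shift, min(ys), max(ys))


def _disc_sdist(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float, r: float) -> np.ndarray:
    """Signed distance to a disc boundary (negative inside)."""
    return np.hypot(xx - cx, yy - cy) - r


def _capsule_sdist(xx: np.ndarray, yy: np.ndarray, p0, p1, width: float) -> np.ndarray:
    """Signed distance to a capsule (segment dilated by width/2)."""
    (x0, y0), (x1, y1) = p0, p1
    vx, vy = x1 - x0, y1 - y0
    L2 = vx * vx + vy * vy
    if L2 == 0:
        return _disc_sdist(xx, yy, x0, y0, width / 2.0)
    t = ((xx - x0) * vx + (yy - y0) * vy) / L2
    t = np.clip(t, 0.0, 1.0)
    dx = xx - (x0 + t * vx)
    dy = yy - (y0 + t * vy)
    return np.hypot(dx, dy) - width / 2.0


def _hand_sdist(spec: SceneSpec, xx: np.ndarray, yy: np.ndarray, shift: int) -> np.ndarray:
    """Signed distance to the union of hand primitives (negative inside)."""
    discs, capsules = _hand_primitives(spec)
    d = np.full(xx.shape, np.inf)
    for cx, cy, r in discs:
        d = np.minimum(d, _disc_sdist(xx, yy, cx + shift, cy, r))
    for p0, p1, w in capsules:
        d = np.minimum(d, _capsule_sdist(xx, yy, (p0[0] + shift, p0[1]),
                                         (p1[0] + shift, p1[1]), w))
    return d


def render_scene(spec: SceneSpec, shift: int = 0) -> np.ndarray:
    """Render one frame: hand plus target disc, translated ``shift`` px right.

    The hand outline is the band of pixels within ``hand_stroke`` inside the
    silhouette boundary (a signed-distance band), the object a filled disc
    drawn on top.  The rasterization is a pure function of integer pixel
    coordinates minus the (shifted) shape centres, so an integer shift
    produces an image that is the exact horizontal translate of the
    unshifted render.

    Raises
    ------
    SceneClippedError
        If any shape would extend beyond the retina at this shift.
    """
    n = spec.retina_size
    xmin, xmax, ymin, ymax = _scene_bounds(spec, shift)
    if xmin < 0 or ymin < 0 or xmax > n - 1 or ymax > n - 1:
        raise SceneClippedError(
            f"scene bounds x[{xmin:.1f},{xmax:.1f}] y[{ymin:.1f},{ymax:.1f}] "
            f"exceed {n}x{n} retina at shift {shift}"
        )
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    img = np.zeros((n, n), dtype=np.float64)
    d = _hand_sdist(spec, xx, yy, shift)
    outline = (d <= 0.0) & (d >= -spec.hand_stroke)
    img[outline] = spec.hand_level
    ox, oy = target_offset(spec)
    cx, cy = spec.hand_centre
    obj = _disc_sdist(xx, yy, cx + ox + shift, cy + oy, spec.object_radius) <= 0.0
    img[obj] = spec.object_level  # object drawn on top of the hand
    return img


def make_sequence(spec: SceneSpec, n_shifts: int = 5, shift_step: int = 5,
                  label: str | None = None) -> SceneSequence:
    """Assemble the rightward-translation sequence for one configuration."""
    if n_shifts < 1:
        raise ValueError("n_shifts must be >= 1")
    shifts = [k * shift_step for k in range(n_shifts)]
    frames = [render_scene(spec, s) for s in shifts]
    if label is None:
        label = location_labels(spec.n_target_locations)[spec.target_location_index]
    return SceneSequence(config_label=label, spec=spec, frames=frames,
                         shift_step=shift_step, n_shifts=n_shifts, shifts=shifts)


def default_scene_spec(retina_size: int = 128, n_target_locations: int = 3,
                       shift_step: int = 5, n_shifts: int = 5,
                       target_location_index: int = 0) -> SceneSpec:
    """Baseline geometry, scaled with the retina and centred on the shift range.

    The hand centre is placed so that the midpoint of the translation range
    sits at the horizontal centre of the retina; all linear dimensions scale
    with ``retina_size / 128`` (semicircle diameter 36 px, object radius
    8 px and hand scale 24 px at the 128-px baseline).
    """
    f = retina_size / 128.0
    x0 = retina_size / 2.0 - (n_shifts - 1) * shift_step / 2.0
    return SceneSpec(
        retina_size=retina_size,
        hand_centre=(x0, retina_size / 2.0),
        n_target_locations=n_target_locations,
        target_location_index=target_location_index,
        semicircle_diameter=36.0 * f,
        object_radius=8.0 * f,
        hand_scale=24.0 * f,
        hand_stroke=1.5 * f,
    )


def build_training_set(n_target_locations: int, retina_size: int = 128,
                       shift_step: int = 5, n_shifts: int = 5) -> list[SceneSequence]:
    """One sequence per hand-relative target location.

    For three locations the sequences are ordered Up, Left, Right; otherwise
    by location index (rightmost first).  Presenting every sequence at every
    shift once constitutes one training epoch.
    """
    if not (1 <= n_target_locations <= 10):
        raise ValueError("n_target_locations must be in 1..10")
    labels = location_labels(n_target_locations)
    order = [1, 2, 0] if n_target_locations == 3 else list(range(n_target_locations))
    seqs = []
    for i in order:
        spec = default_scene_spec(retina_size, n_target_locations, shift_step,
                                  n_shifts, target_location_index=i)
        seqs.append(make_sequence(spec, n_shifts=n_shifts, shift_step=shift_step,
                                  label=labels[i]))
    return seqs


def export_sequences(sequences: list[SceneSequence], out_dir: str | Path) -> None:
    """Write frames as PNG + raw ``.npz`` bundles with a JSON manifest."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for seq in sequences:
        entry = {
            "label": seq.config_label,
            "shift_step": seq.shift_step,
            "n_shifts": seq.n_shifts,
            "shifts": seq.shifts,
            "retina_size": seq.spec.retina_size,
            "n_target_locations": seq.spec.n_target_locations,
            "target_location_index": seq.spec.target_location_index,
            "frames": [],
        }
        for k, frame in enumerate(seq.frames):
            stem = f"{seq.config_label}_shift{seq.shifts[k]:03d}"
            iio.imwrite(out / f"{stem}.png", (frame * 255).astype(np.uint8))
            np.savez_compressed(out / f"{stem}.npz", frame=frame.astype(np.float32))
            entry["frames"].append(stem)
        manifest.append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
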
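"""Seeded synthetic fundus-like photographs with grade-dependent lesions.

The generator makes the whole pipeline testable without any external image
set.  A scene is a circular field of view on a near-black background with a
bright optic disc and a branching vessel tree; diabetic-retinopathy severity
(grade 0-4) controls the lesion content:

* microaneurysms — small dark red dots, 4·g² per image;
* hemorrhages    — larger dark blobs, 2·g per image, grades >= 2 only;
* exudates       — bright yellow-shifted blobs, 3·max(0, g-1) per image;
* grade 4 additionally grows extra tortuous vessel segments
  (a stand-in for neovascularisation).

Grade 0 draws no lesion primitive at all.  Mild per-camera jitter
(brightness and contrast, each within ±10%) emulates the heterogeneity of
multi-clinic photographs.  Every image is deterministic given its seed, and a
scene log of drawn primitives is emitted so tests can assert content without
image analysis.  No claim of clinical realism is made: lesions are photometric
blobs, not pathology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_manifest import ManifestRecord

_RETINA_RGB = np.array([175.0, 88.0, 38.0])      # orange-red fundus tone
_DISC_RGB = np.array([235.0, 195.0, 140.0])      # bright optic disc
_VESSEL_RGB = np.array([110.0, 35.0, 25.0])      # dark red vessels
_MICRO_RGB = np.array([95.0, 28.0, 20.0])        # microaneurysm dots
_HEMORRHAGE_RGB = np.array([80.0, 22.0, 18.0])   # hemorrhage blobs
_EXUDATE_RGB = np.array([240.0, 220.0, 120.0])   # hard-exudate blobs
_BACKGROUND = 8.0                                 # near-black surround

GRADE4_EXTRA_VESSELS = 6


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic fundus scene.

    Lesion multipliers scale the default grade-dependent counts; at the
    defaults counts are non-decreasing in grade and grade 0 has no lesions.
    """

    grade: int
    seed: int
    image_size: int = 256
    microaneurysm_mult: float = 1.0
    hemorrhage_mult: float = 1.0
    exudate_mult: float = 1.0
    neovessel_mult: float = 1.0

    def lesion_counts(self) -> dict[str, int]:
        g = self.grade
        return {
            "microaneurysm": round(self.microaneurysm_mult * 4 * g * g),
            "hemorrhage": round(self.hemorrhage_mult * 2 * g) if g >= 2 else 0,
            "exudate": round(self.exudate_mult * 3 * max(0, g - 1)),
            "neovessel": round(self.neovessel_mult * GRADE4_EXTRA_VESSELS)
            if g >= 4 else 0,
        }


@dataclass
class SceneLog:
    """Record of what was drawn, one entry per primitive."""

    grade: int
    seed: int
    primitives: list[dict] = field(default_factory=list)

    def add(self, kind: str, **attrs) -> None:
        self.primitives.append({"kind": kind, **attrs})

    def count(self, kind: str | None = None) -> int:
        if kind is None:
            return len(self.primitives)
        return sum(1 for p in self.primitives if p["kind"] == kind)

    def lesion_count(self) -> int:
        lesions = {"microaneurysm", "hemorrhage", "exudate", "neovessel"}
        return sum(1 for p in self.primitives if p["kind"] in lesions)

    def to_dict(self) -> dict:
        return {"grade": self.grade, "seed": self.seed,
                "primitives": self.primitives}


def _disk(canvas: np.ndarray, cy: float, cx: float, r: float,
          rgb: np.ndarray, soft: float = 1.0) -> None:
    """Alpha-blend a soft-edged disk onto the float canvas (in place)."""
    size = canvas.shape[0]
    lo_y = max(0, int(cy - r - 2)); hi_y = min(size, int(cy + r + 3))
    lo_x = max(0, int(cx - r - 2)); hi_x = min(size, int(cx + r + 3))
    if lo_y >= hi_y or lo_x >= hi_x:
        return
    yy, xx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    alpha = np.clip((r - d) / soft + 0.5, 0.0, 1.0)[..., None]
    canvas[lo_y:hi_y, lo_x:hi_x] = (
        (1 - alpha) * canvas[lo_y:hi_y, lo_x:hi_x] + alpha * rgb
    )


def _vessel_path(canvas: np.ndarray, rng: np.random.Generator,
                 y: float, x: float, angle: float, length: float,
                 width: float, tortuosity: float, fov_c: float,
                 fov_r: float) -> None:
    """Draw one vessel as a chain of disks along a wiggly path."""
    steps = max(2, int(length))
    for _ in range(steps):
        if (y - fov_c) ** 2 + (x - fov_c) ** 2 > (0.97 * fov_r) ** 2:
            break
        _disk(canvas, y, x, width, _VESSEL_RGB, soft=1.2)
        angle += rng.normal(0.0, tortuosity)
        y += math.sin(angle)
        x += math.cos(angle)


def generate_fundus(params: SceneParams) -> tuple[np.ndarray, int, SceneLog]:
    """Render one synthetic fundus photograph.

    Returns ``(pixels, grade, scene_log)`` with uint8 H×W×3 pixels.  The
    rendering is fully deterministic given ``params``.
    """
    if params.grade not in (0, 1, 2, 3, 4):
        raise ValueError(f"grade {params.grade} outside 0-4")
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    log = SceneLog(grade=params.grade, seed=params.seed)

    canvas = np.full((size, size, 3), _BACKGROUND, dtype=np.float64)
    fov_c = size / 2.0
    fov_r = 0.47 * size

    # retina: circular FOV with a mild radial falloff and fine texture
    yy, xx = np.mgrid[0:size, 0:size]
    d = np.sqrt((yy - fov_c) ** 2 + (xx - fov_c) ** 2)
    inside = np.clip((fov_r - d) / 1.5 + 0.5, 0.0, 1.0)
    falloff = 1.0 - 0.25 * np.clip(d / fov_r, 0.0, 1.0) ** 2
    texture = rng.normal(1.0, 0.02, size=(size, size))
    retina = _RETINA_RGB[None, None, :] * (falloff * texture)[..., None]
    canvas = (1 - inside[..., None]) * canvas + inside[..., None] * retina
    log.add("field_of_view", radius=fov_r)

    # optic disc, off-centre
    disc_angle = rng.uniform(0, 2 * math.pi)
    disc_y = fov_c + 0.55 * fov_r * math.sin(disc_angle)
    disc_x = fov_c + 0.55 * fov_r * math.cos(disc_angle)
    disc_r = 0.085 * size
    _disk(canvas, disc_y, disc_x, disc_r, _DISC_RGB, soft=2.5)
    log.add("optic_disc", y=disc_y, x=disc_x, radius=disc_r)

    # vessel tree: trunks leave the disc, each trunk branches once or twice
    n_trunks = 5
    for _ in range(n_trunks):
        angle = rng.uniform(0, 2 * math.pi)
        length = rng.uniform(0.5, 0.9) * fov_r
        width = rng.uniform(0.008, 0.013) * size
        _vessel_path(canvas, rng, disc_y, disc_x, angle, length, width,
                     tortuosity=0.08, fov_c=fov_c, fov_r=fov_r)
        log.add("vessel", width=width, length=length)
        for _ in range(rng.integers(1, 3)):
            t = rng.uniform(0.3, 0.8)
            by = disc_y + t * length * math.sin(angle)
            bx = disc_x + t * length * math.cos(angle)
            bangle = angle + rng.choice([-1, 1]) * rng.uniform(0.4, 0.9)
            _vessel_path(canvas, rng, by, bx, bangle, 0.5 * length,
                         0.6 * width, tortuosity=0.12, fov_c=fov_c,
                         fov_r=fov_r)
            log.add("vessel", width=0.6 * width, length=0.5 * length)

    def _lesion_site() -> tuple[float, float]:
        # uniform over the FOV interior, away from the rim
        while True:
            y = rng.uniform(fov_c - fov_r, fov_c + fov_r)
            x = rng.uniform(fov_c - fov_r, fov_c + fov_r)
            if (y - fov_c) ** 2 + (x - fov_c) ** 2 < (0.88 * fov_r) ** 2:
                return y, x

    counts = params.lesion_counts()
    for _ in range(counts["microaneurysm"]):
        y, x = _lesion_site()
        r = rng.uniform(0.006, 0.010) * size
        _disk(canvas, y, x, r, _MICRO_RGB, soft=0.8)
        log.add("microaneurysm", y=y, x=x, radius=r)
    for _ in range(counts["hemorrhage"]):
        y, x = _lesion_site()
        r = rng.uniform(0.018, 0.032) * size
        _disk(canvas, y, x, r, _HEMORRHAGE_RGB, soft=2.0)
        log.add("hemorrhage", y=y, x=x, radius=r)
    for _ in range(counts["exudate"]):
        y, x = _lesion_site()
        r = rng.uniform(0.010, 0.022) * size
        _disk(canvas, y, x, r, _EXUDATE_RGB, soft=1.2)
        log.add("exudate", y=y, x=x, radius=r)
    for _ in range(counts["neovessel"]):
        y, x = _lesion_site()
        angle = rng.uniform(0, 2 * math.pi)
        _vessel_path(canvas, rng, y, x, angle, 0.18 * fov_r,
                     0.005 * size, tortuosity=0.45, fov_c=fov_c,
                     fov_r=fov_r)
        log.add("neovessel", y=y, x=x)

    # per-camera jitter: brightness/contrast each within ±10%
    brightness = rng.uniform(0.9, 1.1)
    contrast = rng.uniform(0.9, 1.1)
    mean = canvas.mean()
    canvas = (canvas - mean) * contrast + mean * brightness
    log.add("camera_jitter", brightness=brightness, contrast=contrast)

    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return pixels, params.grade, log


def per_image_seed(dataset_seed: int, index: int) -> int:
    """Derive an independent per-image seed (kept below 2^31)."""
    return (dataset_seed ^ index) & 0x7FFFFFFF


def generate_dataset(n_per_grade: dict[int, int], seed: int,
                     image_size: int = 256,
                     ) -> tuple[dict[str, np.ndarray], list[ManifestRecord],
                                dict[str, SceneLog]]:
    """Generate a labelled synthetic dataset.

    Returns an in-memory image store (id → uint8 array), the manifest, and
    the per-image scene logs.  Ids are ``synth_g{grade}_{i:04d}``.
    """
    store: dict[str, np.ndarray] = {}
    records: list[ManifestRecord] = []
    logs: dict[str, SceneLog] = {}
    index = 0
    for grade in sorted(n_per_grade):
        count = n_per_grade[grade]
        if count < 0:
            raise ValueError(f"negative count for grade {grade}")
        for i in range(count):
            params = SceneParams(grade=grade, seed=per_image_seed(seed, index),
                                 image_size=image_size)
            pixels, _, log = generate_fundus(params)
            image_id = f"synth_g{grade}_{i:04d}"
            store[image_id] = pixels
            logs[image_id] = log
            records.append(ManifestRecord(id=image_id, grade=grade))
            index += 1
    return store, records, logs
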
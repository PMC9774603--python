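"""Procedural face-like image generator with AU-coded geometry.

Real frame-level pain archives are access-restricted, so the package ships a
generator that emulates the structure the method assumes: an elliptical
face foreground whose geometry deforms with the latent pain level, rendered
over configurable backgrounds.  Action-unit intensities are sampled so that
the PSPI score clusters to the requested level, then mapped to geometry:

* AU4 (brow lowerer)      -> brows drop toward the eyes and tilt inward
* AU6/AU7 (orbit tighten) -> eye apertures narrow
* AU9/AU10 (levator)      -> nose-wrinkle strokes appear and darken
* AU43 (eye closure)      -> eyes rendered shut

``deformation_strength`` scales every AU-to-geometry coupling; at 0 the
rendered face is level-independent (a negative control: labels then carry
no pixel signal).  Backgrounds are flat, gaussian noise, or cluttered with
random high-contrast shapes that exercise background shielding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import disk, ellipse, line

from .pspi import (
    AUVector,
    FrameRecord,
    cluster_level,
    compute_pspi,
    frequency_table,
    records_to_frame,
)

__all__ = ["SyntheticSpec", "sample_au_for_level", "render_face",
           "generate_frame", "generate_dataset"]

BACKGROUND_MODES = ("flat", "noise", "clutter")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    frames_per_level: dict[int, int] = field(
        default_factory=lambda: {lvl: 100 for lvl in range(6)}
    )
    image_size: int = 64
    background: str = "flat"
    deformation_strength: float = 1.0
    au_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background not in BACKGROUND_MODES:
            raise ValueError(
                f"background must be one of {BACKGROUND_MODES}, got {self.background!r}"
            )
        if self.deformation_strength < 0:
            raise ValueError("deformation_strength must be >= 0")
        if any(v < 0 for v in self.frames_per_level.values()):
            raise ValueError("frame counts must be >= 0")


def sample_au_for_level(level: int, rng: np.random.Generator,
                        max_tries: int = 1000) -> AUVector:
    """Draw an AUVector whose PSPI clusters to the requested level.

    Level 0 forces the all-zero vector (PSPI 0 admits nothing else).  Other
    levels rejection-sample AU combinations until the clustered PSPI
    matches.
    """
    if not 0 <= level <= 5:
        raise ValueError(f"level must be in 0..5, got {level}")
    if level == 0:
        return AUVector(0, 0, 0, 0, 0, 0)
    targets = {1: (1, 1), 2: (2, 2), 3: (3, 3), 4: (4, 5), 5: (6, 16)}
    lo, hi = targets[level]
    for _ in range(max_tries):
        target = int(rng.integers(lo, hi + 1))
        au = _random_partition(target, rng)
        if au is not None and cluster_level(compute_pspi(au)) == level:
            return au
    raise RuntimeError(f"could not sample an AU vector for level {level}")


def _random_partition(target: int, rng: np.random.Generator) -> AUVector | None:
    # distribute `target` over au4 + max(au6,au7) + max(au9,au10) + au43
    au43 = int(rng.integers(0, 2)) if target >= 1 else 0
    rest = target - au43
    au4 = int(rng.integers(0, min(rest, 5) + 1))
    rest -= au4
    orbit = int(rng.integers(0, min(rest, 5) + 1))
    levator = rest - orbit
    if not 0 <= levator <= 5:
        return None
    au6, au7 = _pair_with_max(orbit, rng)
    au9, au10 = _pair_with_max(levator, rng)
    return AUVector(au4, au6, au7, au9, au10, au43)


def _pair_with_max(m: int, rng: np.random.Generator) -> tuple[int, int]:
    other = int(rng.integers(0, m + 1))
    if rng.random() < 0.5:
        return m, other
    return other, m


def render_face(au: AUVector, spec: SyntheticSpec,
                face_rng: np.random.Generator,
                bg_rng: np.random.Generator) -> np.ndarray:
    """Render one (S, S, 3) uint8 frame for the given action units.

    Face geometry consumes only ``face_rng`` draws, the background only
    ``bg_rng`` draws, so the same face seed yields identical facial pixels
    across background modes.
    """
    S = spec.image_size
    img = _render_background(spec, bg_rng, S)
    k = spec.deformation_strength

    # face ellipse with small position/size jitter
    cy = S / 2 + face_rng.normal(0, 0.01 * S)
    cx = S / 2 + face_rng.normal(0, 0.01 * S)
    ry = 0.38 * S * (1 + face_rng.normal(0, 0.02))
    rx = 0.30 * S * (1 + face_rng.normal(0, 0.02))
    skin = np.array([205, 170, 140]) + face_rng.normal(0, 4, 3)
    rr, cc = ellipse(cy, cx, ry, rx, shape=(S, S))
    img[rr, cc] = np.clip(skin, 0, 255)

    eye_dy = 0.10 * S
    eye_dx = 0.13 * S
    aperture_scale = max(1.0 - 0.17 * k * max(au.au6, au.au7), 0.12)
    closed = k > 0 and au.au43 >= 1
    for sx in (-1, 1):
        ey, ex = cy - eye_dy, cx + sx * eye_dx
        if closed:
            r0, c0 = line(int(ey), int(ex - 0.07 * S), int(ey), int(ex + 0.07 * S))
            _paint(img, r0, c0, (30, 20, 20), S, thick=True)
        else:
            er = max(0.06 * S * aperture_scale, 1.0)
            rr, cc = ellipse(ey, ex, er, 0.07 * S, shape=(S, S))
            img[rr, cc] = (245, 245, 245)
            rr, cc = disk((ey, ex), max(0.03 * S * aperture_scale, 1.0), shape=(S, S))
            img[rr, cc] = (40, 30, 30)
        # brow: drops toward the eye and tilts inward with AU4
        drop = min(0.025 * S * k * au.au4, 0.08 * S)
        by = ey - 0.10 * S + drop
        tilt = min(0.015 * S * k * au.au4, 0.05 * S)
        r0, c0 = line(int(by + (tilt if sx < 0 else 0)), int(ex - 0.08 * S),
                      int(by + (tilt if sx > 0 else 0)), int(ex + 0.08 * S))
        _paint(img, r0, c0, (60, 40, 30), S, thick=True)

    # nose and levator-driven wrinkle strokes
    ny, nx = cy + 0.02 * S, cx
    r0, c0 = line(int(ny - 0.05 * S), int(nx), int(ny + 0.08 * S), int(nx))
    _paint(img, r0, c0, (150, 110, 90), S)
    wrinkle = max(au.au9, au.au10)
    n_strokes = int(round(k * wrinkle))
    for w in range(min(n_strokes, 8)):
        wy = int(ny + 0.01 * S - 0.025 * S * w)
        half = int(0.04 * S)
        r0, c0 = line(wy, int(nx - half), wy - int(0.02 * S), int(nx - half * 3))
        _paint(img, r0, c0, (70, 40, 35), S, thick=True)
        r0, c0 = line(wy, int(nx + half), wy - int(0.02 * S), int(nx + half * 3))
        _paint(img, r0, c0, (70, 40, 35), S, thick=True)

    # mouth: the overall grimace (stretch + opening) co-varies with the
    # latent pain level, the strong global geometry-level coupling
    pspi = compute_pspi(au)
    my = cy + 0.22 * S
    stretch = 0.08 * S * (1 + 0.08 * k * min(pspi, 10))
    opening = 0.012 * S * k * min(pspi, 10)
    if opening >= 1.0:
        rr, cc = ellipse(my, cx, opening, stretch, shape=(S, S))
        img[rr, cc] = (70, 25, 25)
    else:
        r0, c0 = line(int(my), int(cx - stretch), int(my), int(cx + stretch))
        _paint(img, r0, c0, (120, 50, 50), S, thick=True)
    return img.astype(np.uint8)


def _paint(img: np.ndarray, rr: np.ndarray, cc: np.ndarray, color, S: int,
           thick: bool = False) -> None:
    keep = (rr >= 0) & (rr < S) & (cc >= 0) & (cc < S)
    rr, cc = rr[keep], cc[keep]
    img[rr, cc] = color
    if thick:
        rr2 = np.clip(rr + 1, 0, S - 1)
        img[rr2, cc] = color


def _render_background(spec: SyntheticSpec, bg_rng: np.random.Generator,
                       S: int) -> np.ndarray:
    base = bg_rng.uniform(40, 215)
    img = np.full((S, S, 3), base)
    if spec.background == "noise":
        img += bg_rng.normal(0, 25, (S, S, 3))
    elif spec.background == "clutter":
        for _ in range(int(bg_rng.integers(6, 12))):
            color = bg_rng.uniform(0, 255, 3)
            shape_kind = bg_rng.random()
            y, x = bg_rng.uniform(0, S, 2)
            if shape_kind < 0.5:
                h, w = bg_rng.uniform(0.05 * S, 0.3 * S, 2)
                y0, y1 = int(max(y - h / 2, 0)), int(min(y + h / 2, S))
                x0, x1 = int(max(x - w / 2, 0)), int(min(x + w / 2, S))
                img[y0:y1, x0:x1] = color
            else:
                ry, rx = bg_rng.uniform(0.03 * S, 0.18 * S, 2)
                rr, cc = ellipse(y, x, ry, rx, shape=(S, S))
                img[rr, cc] = color
    return np.clip(img, 0, 255)


def generate_frame(level: int, spec: SyntheticSpec, rng: np.random.Generator,
                   frame_id: str | None = None,
                   ) -> tuple[np.ndarray, AUVector, FrameRecord]:
    """Generate one labeled frame for a clustered pain level."""
    face_seed, bg_seed = rng.integers(2**31, size=2)
    face_rng = np.random.default_rng(int(face_seed))
    bg_rng = np.random.default_rng(int(bg_seed))
    au = sample_au_for_level(level, face_rng)
    image = render_face(au, spec, face_rng, bg_rng)
    pspi = compute_pspi(au)
    record = FrameRecord(
        frame_id=frame_id or f"synth_{level}_{int(face_seed):010d}",
        image_path=None,
        pspi=pspi,
        clustered_level=cluster_level(pspi),
        au=au,
    )
    return image, au, record


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path,
                     ) -> tuple[list[FrameRecord], Path]:
    """Write PNG frames + a manifest CSV; returns (records, manifest path).

    Per-level counts follow ``spec.frames_per_level`` exactly.  The manifest
    uses the label-table dialect (frame_id, AU columns, pspi,
    clustered_level, image_path).
    """
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    try:
        images_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {images_dir}: {exc}") from exc
    rng = np.random.default_rng(spec.seed)
    records = []
    for level in sorted(spec.frames_per_level):
        for i in range(spec.frames_per_level[level]):
            frame_id = f"level{level}_frame{i:05d}"
            image, _au, record = generate_frame(level, spec, rng, frame_id=frame_id)
            path = images_dir / f"{frame_id}.png"
            Image.fromarray(image).save(path)
            record.image_path = str(path)
            records.append(record)
    manifest_path = out_dir / "manifest.csv"
    records_to_frame(records).to_csv(manifest_path, index=False)
    freq = frequency_table(records)
    freq.to_frame().to_csv(out_dir / "frequencies.csv", index=False)
    return records, manifest_path
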
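"""Seeded generator of dermoscopy-like image/mask pairs.

Real dermoscopic lesion images are hard to segment because of low contrast
between lesion and skin, irregular lesion borders, and acquisition artifacts
— hairs crossing the field, dark vignettes at the frame corners, and sensor
noise.  This module emulates exactly those difficulty factors on top of a
simple geometric ground truth so the whole pipeline can be exercised without
any downloads:

* the mask is a single star-shaped blob: an ellipse whose boundary radius is
  modulated by a low-frequency random Fourier series (the
  ``border_irregularity`` knob sets the maximum radial deviation);
* the image is a tan skin-toned background with the lesion region tinted
  brown; ``contrast`` in (0, 1] scales the tint (small values give the
  low-contrast transitions that make real lesions hard);
* optional dark curvilinear hair strokes and a dark corner vignette are
  painted over the image only — the mask is never touched by artifacts;
* Gaussian pixel noise is added last, then the image is quantized to 8 bits.

Generation is a pure function of ``(spec, index)``: the per-sample RNG is
seeded from the pair, so datasets are byte-reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

# Arbitrary documented color constants (not dermoscopy statistics): tan skin,
# brown lesion, near-black hair, all in [0, 1] RGB.
SKIN_RGB = (0.80, 0.66, 0.56)
LESION_RGB = (0.42, 0.26, 0.20)
HAIR_RGB = (0.15, 0.12, 0.10)
COLOR_JITTER = 0.04


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic lesion distribution.

    ``lesion_radius_frac`` bounds the ellipse semi-axes as fractions of
    ``min(H, W)``; ``border_irregularity`` is the maximum relative radial
    perturbation of the boundary; ``contrast`` scales the lesion tint;
    ``noise_sd`` is the Gaussian noise standard deviation in [0, 1] intensity
    units.
    """

    size: tuple[int, int] = (256, 256)
    n_samples: int = 16
    lesion_radius_frac: tuple[float, float] = (0.15, 0.32)
    border_irregularity: float = 0.25
    contrast: float = 0.5
    hair_prob: float = 0.5
    vignette_prob: float = 0.3
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_radius_frac
        if not (0 < lo <= hi < 0.5):
            raise ValueError("lesion_radius_frac must satisfy 0 < lo <= hi < 0.5")
        for name in ("hair_prob", "vignette_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must be in (0, 1]")
        if self.border_irregularity < 0 or self.noise_sd < 0:
            raise ValueError("border_irregularity and noise_sd must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Sample:
    """One generated image/mask pair with its provenance."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    index: int
    seed: int


def _sample_rng(spec: SynthSpec, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, index]))


def _boundary_perturbation(rng: np.random.Generator, amplitude: float):
    """A smooth 2*pi-periodic function with max |deviation| = amplitude.

    Truncated Fourier series over harmonics 2..5 only — low frequencies keep
    the blob star-shaped (hence simply connected) for amplitude < 1.
    """
    ks = np.arange(2, 6)
    a = rng.normal(0, 1.0 / ks)
    b = rng.normal(0, 1.0 / ks)
    theta_dense = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    raw = (a[:, None] * np.cos(ks[:, None] * theta_dense)
           + b[:, None] * np.sin(ks[:, None] * theta_dense)).sum(axis=0)
    peak = np.abs(raw).max()
    scale = amplitude / peak if peak > 0 else 0.0

    def perturb(theta: np.ndarray) -> np.ndarray:
        dev = (a[:, None] * np.cos(ks[:, None] * theta.ravel())
               + b[:, None] * np.sin(ks[:, None] * theta.ravel())).sum(axis=0)
        return 1.0 + scale * dev.reshape(theta.shape)

    return perturb


def _lesion_mask(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Binary lesion mask: perturbed rotated ellipse, fully inside the frame."""
    h, w = spec.size
    m = min(h, w)
    lo, hi = spec.lesion_radius_frac
    irr = spec.border_irregularity
    margin = 2.0
    for _ in range(100):
        a_ax = rng.uniform(lo, hi) * m
        b_ax = rng.uniform(lo, hi) * m
        phi = rng.uniform(0, np.pi)
        perturb = _boundary_perturbation(rng, irr)
        reach = max(a_ax, b_ax) * (1.0 + irr) + margin
        if 2 * reach >= min(h, w):
            continue  # cannot fit at this size: redraw
        cy = rng.uniform(reach, h - reach)
        cx = rng.uniform(reach, w - reach)
        rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
        dy, dx = rr - cy, cc - cx
        # rotate into the ellipse frame
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        rho = np.sqrt((u / a_ax) ** 2 + (v / b_ax) ** 2)
        theta = np.arctan2(v / b_ax, u / a_ax)
        mask = rho <= perturb(theta)
        if mask.any():
            return mask.astype(np.uint8)
    raise RuntimeError("could not fit a lesion inside the frame; check SynthSpec radii")


def _draw_hairs(image: np.ndarray, rng: np.random.Generator) -> None:
    """Paint dark quadratic-Bezier strokes (in place)."""
    h, w = image.shape[:2]
    n_hairs = int(rng.integers(2, 6))
    hair = np.array(HAIR_RGB)
    for _ in range(n_hairs):
        pts = rng.uniform([0, 0], [h, w], size=(3, 2))
        t = np.linspace(0, 1, 4 * max(h, w))[:, None]
        curve = ((1 - t) ** 2 * pts[0] + 2 * (1 - t) * t * pts[1] + t ** 2 * pts[2])
        ij = np.round(curve).astype(int)
        keep = (ij[:, 0] >= 0) & (ij[:, 0] < h) & (ij[:, 1] >= 0) & (ij[:, 1] < w)
        ij = ij[keep]
        stroke = np.zeros((h, w), dtype=bool)
        stroke[ij[:, 0], ij[:, 1]] = True
        if rng.random() < 0.5:  # about half the hairs are thicker
            stroke = ndimage.binary_dilation(stroke)
        alpha = rng.uniform(0.6, 0.9)
        image[stroke] = (1 - alpha) * image[stroke] + alpha * hair


def _apply_vignette(image: np.ndarray, rng: np.random.Generator) -> None:
    """Darken toward the corners beyond a central radius (in place)."""
    h, w = image.shape[:2]
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    d = np.hypot(rr - (h - 1) / 2, cc - (w - 1) / 2)
    d_max = np.hypot((h - 1) / 2, (w - 1) / 2)
    start = rng.uniform(0.55, 0.75)
    strength = rng.uniform(0.5, 0.9)
    fall = np.clip((d / d_max - start) / (1 - start), 0, 1) ** 2
    image *= (1.0 - strength * fall)[:, :, None]


def generate_sample(spec: SynthSpec, index: int) -> Sample:
    """Generate one image/mask pair; deterministic in ``(spec, index)``."""
    rng = _sample_rng(spec, index)
    h, w = spec.size
    mask = _lesion_mask(spec, rng)

    skin = np.array(SKIN_RGB) + rng.uniform(-COLOR_JITTER, COLOR_JITTER, 3)
    lesion = np.array(LESION_RGB) + rng.uniform(-COLOR_JITTER, COLOR_JITTER, 3)
    image = np.broadcast_to(skin, (h, w, 3)).copy()
    # lesion tint support equals the mask support exactly, scaled by contrast
    image[mask.astype(bool)] += spec.contrast * (lesion - skin)

    # artifact draws always consume the same RNG stream, applied or not
    hair_on = rng.random() < spec.hair_prob
    _draw_hairs(image if hair_on else image.copy(), rng)
    vignette_on = rng.random() < spec.vignette_prob
    _apply_vignette(image if vignette_on else image.copy(), rng)

    if spec.noise_sd > 0:
        image = image + rng.normal(0, spec.noise_sd, image.shape)
    image = np.clip(image, 0, 1)
    return Sample(image=(image * 255).round().astype(np.uint8),
                  mask=mask, index=index, seed=spec.seed)


def generate_batch(spec: SynthSpec, n: int | None = None, start: int = 0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Arrays (N, 3, H, W) float32 in [0,1] and (N, H, W) uint8 masks."""
    n = spec.n_samples if n is None else n
    samples = [generate_sample(spec, start + i) for i in range(n)]
    images = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    return images.transpose(0, 3, 1, 2), np.stack([s.mask for s in samples])


def generate_dataset(spec: SynthSpec, out_dir: str | Path) -> Path:
    """Write PNG images/masks plus a manifest CSV; return the manifest path.

    Layout mirrors an ISIC-style folder dataset: ``images/`` (RGB PNG),
    ``masks/`` (single-channel PNG, values {0, 255}) and ``manifest.csv``
    with columns image_path, mask_path, seed, index (paths relative to the
    manifest).
    """
    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directories under {out_dir}: {exc}") from exc
    rows = []
    for i in range(spec.n_samples):
        s = generate_sample(spec, i)
        img_rel = f"images/img_{i:04d}.png"
        mask_rel = f"masks/mask_{i:04d}.png"
        Image.fromarray(s.image, mode="RGB").save(out_dir / img_rel)
        Image.fromarray(s.mask * 255, mode="L").save(out_dir / mask_rel)
        rows.append({"image_path": img_rel, "mask_path": mask_rel,
                     "seed": spec.seed, "index": i})
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["image_path", "mask_path", "seed", "index"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest
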
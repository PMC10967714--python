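"""Seeded 2-D brain-MRI-like phantoms with ground truth.

Each phantom is an elliptical "brain" of three concentric tissue bands
(CSF, gray matter, white matter) on a dark background, with a tumor drawn
according to its class:

* glioma      — an irregular, infiltrative blob in the white matter: an
                ellipse whose boundary radius is perturbed by random
                sinusoids, with strong within-tumor intensity modulation;
* meningioma  — a smooth ellipse tangent to the brain surface (tumors of
                the meninges grow along the brain's outer membrane);
* pituitary   — a small round blob at the central inferior position,
                where the pituitary gland sits at the base of the brain;
* no_tumor    — absent.

Tumors are hyperintense (brighter than every tissue), carry a smooth
class-dependent texture modulation, and the whole image receives additive
Gaussian or Rician (magnitude-MRI) noise before clipping to [0, 1].
Everything is a pure function of the spec and its seed, so any other
module can be exercised without downloading data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_io import GrayImage, write_image

__all__ = ["PhantomSpec", "PhantomSample", "CLASSES", "generate", "generate_dataset"]

CLASSES = ("no_tumor", "glioma", "meningioma", "pituitary")

# tissue label codes in the ground-truth map
BG, CSF, GM, WM = 0, 1, 2, 3


@dataclass
class PhantomSpec:
    """Parameters of one synthetic brain slice.

    Tissue intensities must be strictly ordered background < CSF < GM <
    WM < tumor; the defaults give well-separated bands so that intensity
    clustering is a meaningful recovery problem at the default noise.
    ``tumor_area_frac`` is the target tumor area as a fraction of the
    brain area (the pituitary class uses half of it: a small gland).
    """

    size: tuple[int, int] = (128, 128)
    tissue_levels: tuple[float, float, float, float] = (0.0, 0.25, 0.55, 0.8)
    tumor_class: str = "glioma"
    tumor_intensity: float = 0.95
    tumor_area_frac: float = 0.04
    noise_model: str = "gaussian"
    noise_sigma: float = 0.02
    texture_amp: float | None = None  # default 0.1 glioma, 0.02 others
    seed: int = 0

    def validate(self) -> None:
        if self.tumor_class not in CLASSES:
            raise ValueError(f"unknown tumor class: {self.tumor_class!r}")
        levels = (*self.tissue_levels, self.tumor_intensity)
        if any(not (0 <= v <= 1) for v in levels):
            raise ValueError("intensities must lie in [0, 1]")
        if any(a >= b for a, b in zip(levels, levels[1:])):
            raise ValueError(
                "intensities must be strictly ordered bg < CSF < GM < WM < tumor"
            )
        if not (0 < self.tumor_area_frac < 0.5):
            raise ValueError("tumor_area_frac must lie in (0, 0.5)")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model: {self.noise_model!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def effective_texture_amp(self) -> float:
        if self.texture_amp is not None:
            return self.texture_amp
        return 0.1 if self.tumor_class == "glioma" else 0.02


@dataclass
class PhantomSample:
    image: GrayImage
    tissue_labels: np.ndarray  # BG/CSF/GM/WM codes
    tumor_mask: np.ndarray  # bool
    class_label: str
    spec: PhantomSpec = field(repr=False)
    seed: int = 0


def _brain_geometry(spec: PhantomSpec, rng: np.random.Generator):
    rows, cols = spec.size
    cy = rows / 2 + rng.uniform(-0.02, 0.02) * rows
    cx = cols / 2 + rng.uniform(-0.02, 0.02) * cols
    a = 0.42 * rows * rng.uniform(0.95, 1.05)  # vertical semi-axis
    b = 0.36 * cols * rng.uniform(0.95, 1.05)  # horizontal semi-axis
    yy, xx = np.mgrid[0:rows, 0:cols]
    r = np.sqrt(((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2)
    return cy, cx, a, b, yy, xx, r


def _glioma_mask(spec, rng, cy, cx, a, b, yy, xx, r, target_area):
    # irregular blob centred in the white matter (normalized radius < 0.35)
    theta_c = rng.uniform(0, 2 * np.pi)
    rc = rng.uniform(0.0, 0.35)
    ty = cy + rc * a * np.sin(theta_c)
    tx = cx + rc * b * np.cos(theta_c)
    r0 = np.sqrt(target_area / np.pi)
    # radial boundary perturbation: a few random sinusoids, max amplitude 1
    ks = rng.integers(2, 7, size=4)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    amps = rng.uniform(0.5, 1.0, size=4)
    theta = np.arctan2(yy - ty, xx - tx)
    pert = np.zeros_like(theta)
    for k, ph, am in zip(ks, phases, amps):
        pert += am * np.sin(k * theta + ph)
    pert /= np.max(np.abs(pert))
    roughness = 0.35
    radius = r0 * (1.0 + roughness * pert)
    dist = np.sqrt((yy - ty) ** 2 + (xx - tx) ** 2)
    return dist <= radius


def _meningioma_mask(spec, rng, cy, cx, a, b, yy, xx, r, target_area):
    # smooth ellipse tangent to the brain boundary from the inside
    phi = rng.uniform(0, 2 * np.pi)
    ratio = rng.uniform(1.1, 1.5)  # mild elongation along the surface
    rb = np.sqrt(target_area / (np.pi * ratio))  # radial semi-axis
    ra = rb * ratio  # tangential semi-axis
    # boundary point of the brain ellipse along direction phi
    by = cy + a * np.sin(phi)
    bx = cx + b * np.cos(phi)
    # unit inward radial direction
    vy, vx = cy - by, cx - bx
    norm = np.hypot(vy, vx)
    vy, vx = vy / norm, vx / norm
    ty, tx = by + rb * vy, bx + rb * vx
    # tangential unit vector
    uy, ux = -vx, vy
    dr = (yy - ty) * vy + (xx - tx) * vx  # radial coordinate
    dt = (yy - ty) * uy + (xx - tx) * ux  # tangential coordinate
    return (dr / rb) ** 2 + (dt / ra) ** 2 <= 1.0


def _pituitary_mask(spec, rng, cy, cx, a, b, yy, xx, r, target_area):
    # small round blob at the central base (inferior) of the brain
    target_area = target_area / 2.0  # a small gland
    r0 = np.sqrt(target_area / np.pi)
    ty = cy + rng.uniform(0.55, 0.65) * a
    tx = cx + rng.uniform(-0.05, 0.05) * b
    dist = np.sqrt((yy - ty) ** 2 + (xx - tx) ** 2)
    return dist <= r0


def generate(spec: PhantomSpec) -> PhantomSample:
    """Draw one phantom; fully determined by ``spec`` (including seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cy, cx, a, b, yy, xx, r = _brain_geometry(spec, rng)
    brain = r <= 1.0

    tissue = np.full(spec.size, BG, dtype=np.int8)
    tissue[brain & (r > 0.85)] = CSF
    tissue[brain & (r > 0.62) & (r <= 0.85)] = GM
    tissue[brain & (r <= 0.62)] = WM

    bg_l, csf_l, gm_l, wm_l = spec.tissue_levels
    img = np.choose(tissue, [bg_l, csf_l, gm_l, wm_l]).astype(float)

    brain_area = float(brain.sum())
    target_area = spec.tumor_area_frac * brain_area
    if spec.tumor_class == "no_tumor":
        mask = np.zeros(spec.size, dtype=bool)
    else:
        builder = {
            "glioma": _glioma_mask,
            "meningioma": _meningioma_mask,
            "pituitary": _pituitary_mask,
        }[spec.tumor_class]
        mask = builder(spec, rng, cy, cx, a, b, yy, xx, r, target_area) & brain
        if mask.sum() < 9:
            raise ValueError(
                "tumor does not fit the placement constraints; "
                "reduce tumor_area_frac or enlarge the image"
            )
        # smooth within-tumor texture: low-pass filtered white noise
        field_ = gaussian_filter(rng.standard_normal(spec.size), sigma=3.0)
        field_ /= np.max(np.abs(field_))
        img[mask] = spec.tumor_intensity + spec.effective_texture_amp * field_[mask]

    sigma = spec.noise_sigma
    if sigma > 0:
        if spec.noise_model == "gaussian":
            img = img + sigma * rng.standard_normal(spec.size)
        else:  # Rician magnitude noise
            e1 = sigma * rng.standard_normal(spec.size)
            e2 = sigma * rng.standard_normal(spec.size)
            img = np.sqrt((img + e1) ** 2 + e2**2)
    img = np.clip(img, 0.0, 1.0)

    return PhantomSample(
        image=GrayImage(img, source=f"phantom:{spec.tumor_class}:seed={spec.seed}"),
        tissue_labels=tissue,
        tumor_mask=mask,
        class_label=spec.tumor_class,
        spec=spec,
        seed=spec.seed,
    )


def generate_dataset(
    n_per_class: int,
    seed: int = 0,
    classes: tuple[str, ...] = CLASSES,
    base_spec: PhantomSpec | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[PhantomSample], pd.DataFrame]:
    """Class-balanced phantom dataset from one master seed.

    Per-sample seeds are drawn from the master generator, so one master
    seed fixes every sample. With ``out_dir`` given, images and masks are
    written as PNGs and the manifest as ``manifest.csv``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = base_spec or PhantomSpec()
    master = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for cls in classes:
        for i in range(n_per_class):
            s = int(master.integers(0, 2**31 - 1))
            spec = replace(base, tumor_class=cls, seed=s)
            sample = generate(spec)
            samples.append(sample)
            row = {
                "path": "",
                "mask_path": "",
                "class": cls,
                "seed": s,
                "noise_model": spec.noise_model,
                "noise_sigma": spec.noise_sigma,
                "tumor_area_frac": spec.tumor_area_frac,
            }
            if out_path is not None:
                name = f"{cls}_{i:04d}"
                img_file = out_path / f"{name}.png"
                mask_file = out_path / f"{name}_mask.png"
                write_image(sample.image, img_file, bit_depth=16)
                write_image(
                    GrayImage(sample.tumor_mask.astype(float)), mask_file, bit_depth=8
                )
                row["path"] = img_file.name
                row["mask_path"] = mask_file.name
            rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return samples, manifest
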
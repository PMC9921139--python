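"""Dataset reading/writing, preprocessing, augmentation and the ablation
report.

Datasets live on disk as per-sample 8-bit PNG triplets (image, endo
mask, epi mask) plus a JSON manifest recording domain, spacing and the
generator seed.  Masks are stored as 0/255 and thresholded at 128 on
read.  NIfTI inputs are accepted for single 2-D slices.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

from .phantom import ImageSample, boundary_from_mask
from .trainer import ABLATIONS, ModelConfig, TrainConfig, evaluate_model, fit, summarize_records

FORMAT_VERSION = 1


@dataclass
class ManifestEntry:
    image: str
    domain: str = "source"
    spacing: float = 1.0
    endo_mask: Optional[str] = None
    epi_mask: Optional[str] = None


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry]
    format_version: int = FORMAT_VERSION
    seed: Optional[int] = None

    def validate(self, root: Path) -> None:
        for e in self.entries:
            if (e.endo_mask is None) != (e.epi_mask is None):
                raise ValueError(f"entry {e.image} has one mask path but not the other")
            if e.domain == "source" and e.endo_mask is None:
                raise ValueError(f"source entry {e.image} is missing mask paths")
            for p in (e.image, e.endo_mask, e.epi_mask):
                if p is not None and not (root / p).exists():
                    raise FileNotFoundError(root / p)


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.round(np.asarray(arr, dtype=np.float64) * 255.0), 0, 255).astype(np.uint8)


def save_dataset(samples: Sequence[ImageSample], outdir: str | Path,
                 seed: Optional[int] = None) -> DatasetManifest:
    """Write PNG triplets and a manifest.json; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(samples):
        img_name = f"image_{i:04d}.png"
        iio.imwrite(out / img_name, _to_uint8(s.image))
        entry = ManifestEntry(image=img_name, domain=s.domain, spacing=s.spacing)
        if s.labeled:
            entry.endo_mask = f"endo_{i:04d}.png"
            entry.epi_mask = f"epi_{i:04d}.png"
            iio.imwrite(out / entry.endo_mask, _to_uint8(s.endo_mask))
            iio.imwrite(out / entry.epi_mask, _to_uint8(s.epi_mask))
        entries.append(entry)
    manifest = DatasetManifest(entries=entries, seed=seed)
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2))
    return manifest


def read_manifest(directory: str | Path) -> DatasetManifest:
    root = Path(directory)
    raw = json.loads((root / "manifest.json").read_text())
    manifest = DatasetManifest(
        entries=[ManifestEntry(**e) for e in raw["entries"]],
        format_version=raw.get("format_version", FORMAT_VERSION),
        seed=raw.get("seed"),
    )
    manifest.validate(root)
    return manifest


def _read_image(path: Path) -> np.ndarray:
    """Grayscale 2-D float array in [0, 1] from PNG/TIFF or 2-D NIfTI."""
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        arr = np.asanyarray(nib.load(str(path)).dataobj).squeeze()
    else:
        arr = np.asarray(iio.imread(path)).squeeze()
        if arr.ndim == 3:  # RGB(A) -> luminance
            arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr = arr / 255.0 if arr.max() <= 255 else arr / arr.max()
    return arr


def _center_square(arr: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Center-crop the long axis so the image is square (pad if degenerate)."""
    h, w = arr.shape
    side = min(h, w)
    top, left = (h - side) // 2, (w - side) // 2
    return arr[top:top + side, left:left + side]


def load_sample(entry: ManifestEntry, root: str | Path = ".",
                size: int = 256, boundary_width: int = 2) -> ImageSample:
    """Read, square-crop and resize one manifest entry to ``size`` pixels.

    Images are resampled bilinearly and rescaled to [0, 1]; masks use
    nearest-neighbour resampling so they stay binary.
    """
    root = Path(root)
    img = _center_square(_read_image(root / entry.image))
    if img.shape != (size, size):
        img = resize(img, (size, size), order=1, anti_aliasing=True)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    masks = {}
    for key in ("endo_mask", "epi_mask"):
        rel = getattr(entry, key)
        if rel is None:
            masks[key] = None
            continue
        raw = np.asarray(iio.imread(root / rel)).squeeze()
        if raw.ndim != 2:
            raise ValueError(f"{rel}: mask must be 2-D")
        m = _center_square(raw >= 128)
        if m.shape != (size, size):
            m = resize(m.astype(np.float32), (size, size), order=0,
                       anti_aliasing=False) >= 0.5
        masks[key] = m
    boundary = None
    if masks["endo_mask"] is not None and masks["epi_mask"] is not None:
        boundary = np.maximum(boundary_from_mask(masks["endo_mask"], boundary_width),
                              boundary_from_mask(masks["epi_mask"], boundary_width))
    return ImageSample(image=img, endo_mask=masks["endo_mask"],
                       epi_mask=masks["epi_mask"], boundary_map=boundary,
                       domain=entry.domain, spacing=entry.spacing)


def load_dataset(directory: str | Path, size: int = 256) -> list[ImageSample]:
    manifest = read_manifest(directory)
    return [load_sample(e, directory, size) for e in manifest.entries]


# ----------------------------------------------------------------------
# augmentation

@dataclass
class AugmentConfig:
    """Probabilities and ranges for the three augmentation families:
    random crop-and-resize, salt-and-pepper corruption, intensity jitter."""

    crop_prob: float = 0.5
    crop_frac_range: tuple[float, float] = (0.75, 1.0)
    salt_pepper_prob: float = 0.5
    salt_pepper_rate: float = 0.02
    intensity_prob: float = 0.5
    gain_range: tuple[float, float] = (0.8, 1.2)
    bias_range: tuple[float, float] = (-0.1, 0.1)

    def validate(self) -> None:
        lo, hi = self.crop_frac_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"crop fractions must lie in (0, 1], got {self.crop_frac_range}")


def augment(sample: ImageSample, rng: np.random.Generator,
            cfg: AugmentConfig | None = None) -> ImageSample:
    """Randomly crop-and-resize (geometry shared by image, masks and
    boundary), add salt-and-pepper noise and jitter intensity (image only)."""
    cfg = cfg or AugmentConfig()
    cfg.validate()
    img = sample.image.copy()
    endo, epi, bnd = sample.endo_mask, sample.epi_mask, sample.boundary_map
    size = img.shape[0]

    if rng.random() < cfg.crop_prob:
        frac = rng.uniform(*cfg.crop_frac_range)
        side = max(8, int(round(frac * size)))
        top = rng.integers(0, size - side + 1)
        left = rng.integers(0, size - side + 1)

        def _crop_resize(a, order):
            c = a[top:top + side, left:left + side]
            r = resize(c.astype(np.float32), (size, size), order=order,
                       anti_aliasing=(order > 0))
            return r

        img = np.clip(_crop_resize(img, 1), 0.0, 1.0)
        if endo is not None:
            endo = _crop_resize(endo, 0) >= 0.5
        if epi is not None:
            epi = _crop_resize(epi, 0) >= 0.5
        if bnd is not None:
            bnd = (_crop_resize(bnd, 0) >= 0.5).astype(np.float32)

    if rng.random() < cfg.salt_pepper_prob:
        flip = rng.random(img.shape) < cfg.salt_pepper_rate
        salt = rng.random(img.shape) < 0.5
        img = np.where(flip, np.where(salt, 1.0, 0.0), img)

    if rng.random() < cfg.intensity_prob:
        gain = rng.uniform(*cfg.gain_range)
        bias = rng.uniform(*cfg.bias_range)
        img = np.clip(gain * img + bias, 0.0, 1.0)

    return ImageSample(image=img.astype(np.float32), endo_mask=endo, epi_mask=epi,
                       boundary_map=bnd, domain=sample.domain, spacing=sample.spacing)


# ----------------------------------------------------------------------
# ablation report

def run_ablation(base_cfg: TrainConfig, source: Sequence[ImageSample],
                 target_pool: Sequence[ImageSample],
                 target_eval: Sequence[ImageSample],
                 model_cfg: ModelConfig | None = None,
                 arms: Sequence[str] = ABLATIONS) -> list[dict]:
    """Train every ablation arm with shared seed/data; return a table of
    mean HD/DI/JI per structure per arm on labeled target samples."""
    rows = []
    for arm in arms:
        cfg = replace(base_cfg, ablation=arm)
        result = fit(cfg, source, target_pool if arm != "no_da" else (), model_cfg)
        summary = summarize_records(evaluate_model(result.model, target_eval,
                                                   batch_size=cfg.batch_size))
        for structure, mets in summary.items():
            rows.append({"arm": arm, "structure": structure,
                         "hd": mets["hd"], "di": mets["di"], "ji": mets["ji"]})
    return rows


def write_csv(rows: Sequence[dict], path: str | Path) -> None:
    rows = list(rows)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


def read_csv(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        out = []
        for row in csv.DictReader(fh):
            conv = {}
            for k, v in row.items():
                try:
                    conv[k] = int(v)
                except ValueError:
                    try:
                        conv[k] = float(v)
                    except ValueError:
                        conv[k] = v
            out.append(conv)
        return out
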
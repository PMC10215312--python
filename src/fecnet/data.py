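"""Dataset handling: folder ingestion, augmentation, folds, synthetic images.

The synthetic generator renders the four stool morphologies over cluttered
outdoor-style backgrounds (leaf, stone and twig distractors) so the whole
pipeline — training included — runs without any downloaded data.  Rendering
is fully determined by the spec seed: the same spec produces byte-identical
files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage
from skimage import transform as sktransform
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)

__all__ = [
    "CLASS_NAMES",
    "DatasetInventory",
    "ImageFolderDataset",
    "AugmentationPlan",
    "SyntheticSpec",
    "load_image_folder",
    "augment_image",
    "augment_dataset",
    "kfold_split",
    "generate_synthetic_dataset",
    "render_sample",
]

CLASS_NAMES = ("diarrhea", "lack_of_water", "normal", "soft_stool")

IMG_EXTENSIONS = {".png", ".jpg", ".jpeg"}


class InvalidSpecError(ValueError):
    pass


# ------------------------------------------------------------------ inventory
@dataclass
class DatasetInventory:
    class_names: tuple[str, ...]
    items: list[tuple[Path, int]]  # (path, label)

    @property
    def counts(self) -> dict[str, int]:
        c = {name: 0 for name in self.class_names}
        for _, label in self.items:
            c[self.class_names[label]] += 1
        return c

    @property
    def total(self) -> int:
        return len(self.items)

    def proportions(self) -> dict[str, float]:
        t = self.total
        return {k: v / t for k, v in self.counts.items()}

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("class,count\n")
            for name, n in self.counts.items():
                fh.write(f"{name},{n}\n")


class ImageFolderDataset:
    """Decodes inventory items as RGB float arrays resized to a square."""

    def __init__(self, inventory: DatasetInventory, image_size: int = 224):
        self.inventory = inventory
        self.image_size = image_size

    def __len__(self) -> int:
        return self.inventory.total

    def load_array(self, index: int) -> np.ndarray:
        """CHW float32 in [0, 1]."""
        path, _ = self.inventory.items[index]
        with Image.open(path) as im:
            im = im.convert("RGB").resize(
                (self.image_size, self.image_size), Image.BILINEAR
            )
            arr = np.asarray(im, dtype=np.float32) / 255.0
        return arr.transpose(2, 0, 1)

    def __getitem__(self, index: int) -> tuple[np.ndarray, int]:
        return self.load_array(index), self.inventory.items[index][1]

    @property
    def labels(self) -> np.ndarray:
        return np.array([label for _, label in self.inventory.items])


def load_image_folder(
    root, image_size: int = 224
) -> tuple[DatasetInventory, ImageFolderDataset]:
    """Scan a class-per-directory tree of JPEG/PNG images.

    Empty class directories trigger a warning; unreadable files are skipped
    with a logged warning; an empty root is an error.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir()) if root.is_dir() else []
    if not class_dirs:
        raise InvalidSpecError(f"no class directories under {root}")
    names = tuple(d.name for d in class_dirs)
    items: list[tuple[Path, int]] = []
    for label, d in enumerate(class_dirs):
        files = sorted(
            p for p in d.iterdir() if p.suffix.lower() in IMG_EXTENSIONS
        )
        if not files:
            warnings.warn(f"class directory {d} contains no images")
        for p in files:
            try:
                with Image.open(p) as im:
                    im.verify()
            except Exception as exc:  # corrupt file: skip, keep going
                log.warning("skipping unreadable image %s (%s)", p, exc)
                continue
            items.append((p, label))
    inv = DatasetInventory(class_names=names, items=items)
    return inv, ImageFolderDataset(inv, image_size)


# --------------------------------------------------------------- augmentation
@dataclass(frozen=True)
class AugmentationPlan:
    """One randomly parameterized variant per original image.

    Half the images get a Gaussian blur (sigma up to 0.5); contrast is always
    jittered; Gaussian noise is always added, sampled once per pixel (shared
    across channels) for half the images and per pixel-and-channel otherwise;
    a fifth of the images get a brightness shift; every image gets an affine
    warp (scale/translate/rotate/shear).
    """

    blur_prob: float = 0.5
    blur_sigma_max: float = 0.5
    contrast_range: tuple[float, float] = (0.75, 1.25)
    noise_shared_prob: float = 0.5
    noise_sigma: float = 0.03
    brightness_prob: float = 0.2
    brightness_delta: float = 0.2
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_frac: float = 0.1
    rotate_deg: float = 25.0
    shear_deg: float = 8.0
    variants_per_image: int = 1

    def __post_init__(self):
        if self.variants_per_image != 1:
            raise InvalidSpecError("the protocol appends exactly one variant per image")
        if not 0.0 <= self.blur_sigma_max <= 0.5:
            raise InvalidSpecError("blur sigma must stay within [0, 0.5]")


def augment_image(
    img: np.ndarray, plan: AugmentationPlan, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """Apply the augmentation protocol to one HWC float image in [0, 1]."""
    img = np.asarray(img, dtype=np.float64)
    applied: dict[str, object] = {}

    if rng.random() < plan.blur_prob:
        sigma = rng.uniform(0.0, plan.blur_sigma_max)
        img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
        applied["blur"] = sigma

    factor = rng.uniform(*plan.contrast_range)
    img = (img - 0.5) * factor + 0.5
    applied["contrast"] = factor

    shared = rng.random() < plan.noise_shared_prob
    if shared:
        noise = rng.normal(0.0, plan.noise_sigma, img.shape[:2])[:, :, None]
    else:
        noise = rng.normal(0.0, plan.noise_sigma, img.shape)
    img = img + noise
    applied["noise_shared"] = shared

    if rng.random() < plan.brightness_prob:
        delta = rng.uniform(-plan.brightness_delta, plan.brightness_delta)
        img = img + delta
        applied["brightness"] = delta

    h, w = img.shape[:2]
    scale = rng.uniform(*plan.scale_range)
    rot = np.deg2rad(rng.uniform(-plan.rotate_deg, plan.rotate_deg))
    shear = np.deg2rad(rng.uniform(-plan.shear_deg, plan.shear_deg))
    tx = rng.uniform(-plan.translate_frac, plan.translate_frac) * w
    ty = rng.uniform(-plan.translate_frac, plan.translate_frac) * h
    centering = sktransform.AffineTransform(translation=(-w / 2, -h / 2))
    tf = sktransform.AffineTransform(
        scale=scale, rotation=rot, shear=shear, translation=(tx, ty)
    )
    full = centering + tf + sktransform.AffineTransform(translation=(w / 2, h / 2))
    img = sktransform.warp(np.clip(img, 0, 1), full.inverse, mode="edge")
    applied["affine"] = {
        "scale": scale,
        "rotate_rad": rot,
        "shear_rad": shear,
        "translate": (tx, ty),
    }
    return np.clip(img, 0.0, 1.0).astype(np.float32), applied


def augment_dataset(
    inventory: DatasetInventory,
    plan: AugmentationPlan,
    seed: int = 0,
    suffix: str = "_aug",
) -> tuple[DatasetInventory, list[dict]]:
    """Append exactly one augmented variant per original, on disk.

    Returns the doubled inventory (originals first, variants after, same
    label) and a per-variant record of which transforms were applied.
    """
    rng = np.random.default_rng(seed)
    new_items = list(inventory.items)
    records: list[dict] = []
    for path, label in inventory.items:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
        aug, applied = augment_image(arr, plan, rng)
        out_path = path.with_name(path.stem + suffix + ".png")
        Image.fromarray((aug * 255).round().astype(np.uint8)).save(out_path)
        new_items.append((out_path, label))
        records.append({"source": str(path), "variant": str(out_path), **applied})
    return DatasetInventory(inventory.class_names, new_items), records


# ---------------------------------------------------------------------- folds
def kfold_split(
    inventory: DatasetInventory | int, folds: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint, covering train/test index partitions (sizes differ ≤ 1)."""
    if folds < 2:
        raise InvalidSpecError("at least two folds are required")
    n = inventory if isinstance(inventory, int) else inventory.total
    if n < folds:
        raise InvalidSpecError(f"cannot split {n} items into {folds} folds")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in kf.split(np.arange(n))]


# ------------------------------------------------------------ synthetic data
@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the four-morphology fixture generator."""

    image_size: int = 128
    n_per_class: int | tuple[int, int, int, int] = 20
    distractor_density: float = 1.0
    background_clutter_level: float = 1.0
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise InvalidSpecError("image_size must be at least 64")

    def count_for(self, class_idx: int) -> int:
        if isinstance(self.n_per_class, int):
            return self.n_per_class
        return self.n_per_class[class_idx]


def _jitter(rng, color, amount=12):
    return tuple(
        int(np.clip(c + rng.integers(-amount, amount + 1), 0, 255)) for c in color
    )


def _ellipse_points(cx, cy, rx, ry, angle, n=20):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = rx * np.cos(t)
    y = ry * np.sin(t)
    ca, sa = np.cos(angle), np.sin(angle)
    return [(cx + ca * xi - sa * yi, cy + sa * xi + ca * yi) for xi, yi in zip(x, y)]


def _draw_background(draw, rng, s, spec: SyntheticSpec):
    # large soft blotches give the ground a mottled look
    n_blotch = rng.poisson(3 * spec.background_clutter_level)
    for _ in range(n_blotch):
        cx, cy = rng.uniform(0, s, 2)
        rx, ry = rng.uniform(s / 6, s / 3, 2)
        color = _jitter(rng, (118, 108, 92), 20)
        draw.polygon(_ellipse_points(cx, cy, rx, ry, rng.uniform(0, np.pi)), fill=color)
    # distractors: leaf-, stone- and twig-like shapes
    n_d = rng.poisson(5 * spec.distractor_density)
    for _ in range(n_d):
        kind = rng.integers(3)
        cx, cy = rng.uniform(0, s, 2)
        if kind == 0:  # leaf
            rx = rng.uniform(s / 16, s / 9)
            pts = _ellipse_points(cx, cy, rx, rx * rng.uniform(0.25, 0.45),
                                  rng.uniform(0, np.pi))
            draw.polygon(pts, fill=_jitter(rng, (96, 104, 52), 18))
        elif kind == 1:  # stone
            rx, ry = rng.uniform(s / 24, s / 11, 2)
            pts = _ellipse_points(cx, cy, rx, ry, rng.uniform(0, np.pi))
            draw.polygon(pts, fill=_jitter(rng, (138, 134, 128), 18))
        else:  # twig
            ang = rng.uniform(0, np.pi)
            length = rng.uniform(s / 8, s / 3)
            dx, dy = np.cos(ang) * length / 2, np.sin(ang) * length / 2
            draw.line(
                [(cx - dx, cy - dy), (cx + dx, cy + dy)],
                fill=_jitter(rng, (82, 62, 40), 14),
                width=max(1, int(s / 64)),
            )


def _foreground(draw, mask_draw, rng, s, class_name: str):
    cx = s / 2 + rng.uniform(-s / 8, s / 8)
    cy = s / 2 + rng.uniform(-s / 8, s / 8)
    if class_name == "lack_of_water":
        # cluster of hard-edged near-spherical clumps
        for _ in range(rng.integers(3, 7)):
            r = rng.uniform(s / 15, s / 9)
            ox, oy = rng.uniform(-s / 7, s / 7, 2)
            box = (cx + ox - r, cy + oy - r, cx + ox + r, cy + oy + r)
            draw.ellipse(box, fill=_jitter(rng, (72, 50, 30), 8),
                         outline=(40, 28, 16), width=max(1, int(s / 80)))
            mask_draw.ellipse(box, fill=255)
    elif class_name == "normal":
        # segmented elongated strand with visible gaps
        ang = rng.uniform(0, np.pi)
        curv = rng.uniform(-0.25, 0.25)
        r = s / 13
        n_seg = int(rng.integers(6, 10))
        t0 = -(n_seg - 1) / 2
        for i in range(n_seg):
            t = (t0 + i) * 1.85 * r
            a = ang + curv * (t0 + i) * 0.18
            px = cx + np.cos(a) * t
            py = cy + np.sin(a) * t
            rr = r * rng.uniform(0.85, 1.1)
            box = (px - rr, py - rr, px + rr, py + rr)
            draw.ellipse(box, fill=_jitter(rng, (104, 72, 40), 8),
                         outline=(60, 40, 22), width=max(1, int(s / 100)))
            mask_draw.ellipse(box, fill=255)
    elif class_name == "soft_stool":
        # smooth glossy irregular blob with a specular highlight
        color = _jitter(rng, (134, 96, 54), 8)
        hx = hy = None
        for _ in range(rng.integers(4, 7)):
            rx, ry = rng.uniform(s / 10, s / 6, 2)
            ox, oy = rng.uniform(-s / 9, s / 9, 2)
            pts = _ellipse_points(cx + ox, cy + oy, rx, ry, rng.uniform(0, np.pi))
            draw.polygon(pts, fill=color)
            mask_draw.polygon(pts, fill=255)
            if hx is None:
                hx, hy = cx + ox - rx / 3, cy + oy - ry / 3
        hr = s / 18
        draw.ellipse((hx - hr, hy - hr, hx + hr, hy + hr), fill=(225, 212, 190))
    elif class_name == "diarrhea":
        # low-contrast diffuse amorphous stain (handled via alpha overlay)
        for _ in range(rng.integers(9, 15)):
            rx, ry = rng.uniform(s / 9, s / 4.5, 2)
            ox, oy = rng.uniform(-s / 4.5, s / 4.5, 2)
            pts = _ellipse_points(cx + ox, cy + oy, rx, ry, rng.uniform(0, np.pi))
            alpha = int(rng.integers(36, 80))
            draw.polygon(pts, fill=(108, 86, 58, alpha))
            mask_draw.polygon(pts, fill=255)
    else:  # pragma: no cover
        raise InvalidSpecError(f"unknown class {class_name!r}")


def render_sample(
    class_name: str, rng: np.random.Generator, spec: SyntheticSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Render one image; returns (HWC uint8 image, boolean foreground mask)."""
    s = spec.image_size
    base = _jitter(rng, (122, 112, 96), 10)
    img = Image.new("RGB", (s, s), base)
    draw = ImageDraw.Draw(img)
    mask = Image.new("L", (s, s), 0)
    mask_draw = ImageDraw.Draw(mask)
    _draw_background(draw, rng, s, spec)
    if class_name == "diarrhea":
        overlay = Image.new("RGBA", (s, s), (0, 0, 0, 0))
        _foreground(ImageDraw.Draw(overlay), mask_draw, rng, s, class_name)
        img = Image.alpha_composite(img.convert("RGBA"), overlay).convert("RGB")
    else:
        _foreground(draw, mask_draw, rng, s, class_name)
    arr = np.asarray(img, dtype=np.float64) / 255.0
    arr = arr + rng.normal(0.0, spec.noise_sigma, arr.shape)
    arr = (np.clip(arr, 0, 1) * 255).round().astype(np.uint8)
    return arr, np.asarray(mask) > 0


def generate_synthetic_dataset(
    spec: SyntheticSpec, root, with_masks: bool = False
) -> DatasetInventory:
    """Write a class-per-directory PNG tree; byte-identical for equal specs."""
    root = Path(root)
    items: list[tuple[Path, int]] = []
    for label, name in enumerate(CLASS_NAMES):
        cls_dir = root / name
        cls_dir.mkdir(parents=True, exist_ok=True)
        for i in range(spec.count_for(label)):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, label, i])
            )
            arr, mask = render_sample(name, rng, spec)
            path = cls_dir / f"{name}_{i:05d}.png"
            Image.fromarray(arr).save(path)
            if with_masks:
                Image.fromarray(mask.astype(np.uint8) * 255).save(
                    cls_dir / f"{name}_{i:05d}_mask.png"
                )
            items.append((path, label))
    return DatasetInventory(class_names=CLASS_NAMES, items=items)
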
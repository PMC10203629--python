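"""Image datasets: folder I/O, stratified splitting, augmentation, and a
synthetic tomato-leaf-disease image generator.

The real study data is the PlantVillage tomato subset: 18,835 leaf images
in ten categories (nine diseases plus healthy), laid out as one directory
per class.  That layout is what :func:`load_image_folder` reads, so the
public dataset can be dropped in unchanged.  Because the download is large
and external, the package also ships :func:`generate_synthetic_dataset`,
which renders a small 10-class stand-in with the same directory structure,
the same class-imbalance profile (scaled down), and class-specific lesion
morphology — enough signal for the full pipeline to be exercised and for a
classifier to demonstrably learn the classes.

Splitting follows the study protocol: a random 80/10/10 train/val/test
partition, stratified per class with largest-remainder apportionment so the
split is exact for any input.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

# Per-class image counts of the PlantVillage tomato subset (18,835 total).
TOMATO_CLASS_COUNTS: dict[str, int] = {
    "bacterial_spot": 2127,
    "early_blight": 1000,
    "healthy": 1591,
    "late_blight": 1909,
    "leaf_mold": 1000,
    "septoria_leaf_spot": 1771,
    "two_spotted_spider_mite": 1676,
    "target_spot": 1404,
    "mosaic_virus": 1000,
    "yellow_leaf_curl_virus": 5357,
}

_IMAGE_EXTS = {".png", ".jpg", ".jpeg"}


@dataclass
class LabeledImageSet:
    """Images with integer labels and an ordered class vocabulary."""

    images: list[np.ndarray]
    labels: np.ndarray
    class_names: list[str]
    split_tag: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        k = len(self.class_names)
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= k):
            raise ValueError("labels must lie in [0, num_classes)")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.num_classes)

    def subset(self, indices: np.ndarray, split_tag: str = "") -> "LabeledImageSet":
        return LabeledImageSet(
            [self.images[i] for i in indices],
            self.labels[indices],
            self.class_names,
            split_tag or self.split_tag,
        )


@dataclass(frozen=True)
class SyntheticClassRecipe:
    """How to render one disease class: background hue band, lesion count
    and radius ranges, lesion colour, and pixel-noise level."""

    class_id: int
    name: str
    background_hue: tuple[float, float]  # HSV hue in [0, 1]
    lesion_count: tuple[int, int]
    lesion_radius: tuple[float, float]  # pixels
    lesion_color: tuple[int, int, int]
    texture_noise_sd: float = 8.0


def default_recipes() -> list[SyntheticClassRecipe]:
    """Ten recipes keyed to the tomato disease phenotypes: spot diseases get
    many small dark lesions, blights get large patches, viral yellowing
    shifts the whole background hue, healthy leaves get none."""
    # Each class gets its own background hue band: foliar diseases shift
    # whole-leaf colour (chlorosis, necrosis, mold cover), and the distinct
    # bands are what makes the classes certifiably separable at desk scale.
    r = SyntheticClassRecipe
    return [
        r(0, "bacterial_spot", (0.20, 0.22), (15, 25), (1.5, 3.0), (45, 30, 15)),
        r(1, "early_blight", (0.23, 0.25), (3, 6), (5.0, 9.0), (120, 70, 30)),
        r(2, "healthy", (0.32, 0.34), (0, 0), (0.0, 0.0), (0, 0, 0)),
        r(3, "late_blight", (0.26, 0.28), (2, 4), (8.0, 14.0), (70, 75, 60)),
        r(4, "leaf_mold", (0.29, 0.31), (4, 8), (4.0, 8.0), (200, 180, 80)),
        r(5, "septoria_leaf_spot", (0.35, 0.37), (10, 18), (2.0, 4.0), (185, 185, 170)),
        r(6, "two_spotted_spider_mite", (0.38, 0.40), (20, 35), (1.0, 2.0), (215, 205, 120)),
        r(7, "target_spot", (0.17, 0.19), (5, 9), (3.0, 6.0), (140, 100, 60)),
        r(8, "mosaic_virus", (0.41, 0.43), (6, 10), (6.0, 10.0), (150, 190, 90)),
        r(9, "yellow_leaf_curl_virus", (0.12, 0.15), (3, 5), (10.0, 16.0), (230, 210, 90)),
    ]


def default_class_counts(scale: float = 1.0 / 50.0) -> list[int]:
    """PlantVillage tomato class counts scaled down (default 1/50 -> 377
    images total), preserving the ~5:1 imbalance."""
    return [round(c * scale) for c in TOMATO_CLASS_COUNTS.values()]


def validate_recipes(recipes: list[SyntheticClassRecipe]) -> None:
    """Classes must be pairwise separable: every pair differs in lesion
    colour, lesion count range, or lesion radius range."""
    for i, a in enumerate(recipes):
        for b in recipes[i + 1 :]:
            if (
                a.lesion_color == b.lesion_color
                and a.lesion_count == b.lesion_count
                and a.lesion_radius == b.lesion_radius
            ):
                raise ValueError(
                    f"recipes {a.name!r} and {b.name!r} are indistinguishable"
                )


def _render_image(
    recipe: SyntheticClassRecipe, size: int, rng: np.random.Generator
) -> np.ndarray:
    hue = rng.uniform(*recipe.background_hue)
    sat = rng.uniform(0.55, 0.75)
    val = rng.uniform(0.45, 0.6)
    base = np.array(colorsys.hsv_to_rgb(hue, sat, val)) * 255.0
    # Smooth vein-like texture: low-resolution noise upsampled bilinearly.
    lowres = rng.normal(0.0, 18.0, (8, 8, 1)).astype(np.float32)
    tex = np.asarray(
        Image.fromarray(lowres[:, :, 0]).resize((size, size), Image.BILINEAR)
    )[:, :, None]
    img = base[None, None, :] + tex
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    n_lesions = int(rng.integers(recipe.lesion_count[0], recipe.lesion_count[1] + 1))
    color = np.array(recipe.lesion_color, dtype=np.float32)
    for _ in range(n_lesions):
        cy = rng.uniform(0.1 * size, 0.9 * size)
        cx = rng.uniform(0.1 * size, 0.9 * size)
        radius = rng.uniform(*recipe.lesion_radius)
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        alpha = np.clip(1.5 - dist / max(radius, 1e-6), 0.0, 1.0)[:, :, None] * 0.85
        img = img * (1.0 - alpha) + color[None, None, :] * alpha
    img += rng.normal(0.0, recipe.texture_noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_synthetic_dataset(
    out_dir: str | Path | None = None,
    recipes: list[SyntheticClassRecipe] | None = None,
    counts: list[int] | None = None,
    image_size: int = 64,
    seed: int = 0,
) -> LabeledImageSet:
    """Render a class-per-directory synthetic leaf-disease dataset.

    With the defaults this produces 377 images of 64x64 pixels across ten
    classes with the PlantVillage imbalance profile.  Fully deterministic
    under ``seed`` (two runs produce byte-identical PNG files).  When
    ``out_dir`` is None the images are only returned in memory.
    """
    recipes = recipes if recipes is not None else default_recipes()
    counts = counts if counts is not None else default_class_counts()
    if len(counts) != len(recipes):
        raise ValueError("counts and recipes must have equal length")
    for rcp, n in zip(recipes, counts):
        if n <= 0:
            raise ValueError(f"class {rcp.name!r} has non-positive count {n}")
    validate_recipes(recipes)
    rng = np.random.default_rng(seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    class_names = [r.name for r in recipes]
    for class_id, (recipe, n) in enumerate(zip(recipes, counts)):
        cls_dir = None
        if out_dir is not None:
            cls_dir = Path(out_dir) / recipe.name
            cls_dir.mkdir(parents=True, exist_ok=True)
        for i in range(n):
            img = _render_image(recipe, image_size, rng)
            images.append(img)
            labels.append(class_id)
            if cls_dir is not None:
                Image.fromarray(img).save(cls_dir / f"{recipe.name}_{i:04d}.png")
    return LabeledImageSet(images, np.array(labels), class_names, "all")


def load_image_folder(root: str | Path) -> LabeledImageSet:
    """Read a class-per-directory image tree; class ids follow sorted
    directory names; all images are decoded to 8-bit RGB."""
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(f"{root} must contain at least 2 class directories")
    images: list[np.ndarray] = []
    labels: list[int] = []
    for class_id, d in enumerate(class_dirs):
        files = sorted(
            f for f in d.iterdir() if f.suffix.lower() in _IMAGE_EXTS
        )
        if not files:
            raise ValueError(f"class directory {d} contains no images")
        for f in files:
            try:
                with Image.open(f) as im:
                    images.append(np.asarray(im.convert("RGB")))
            except (UnidentifiedImageError, OSError) as exc:
                raise ValueError(f"cannot decode image file {f}") from exc
            labels.append(class_id)
    return LabeledImageSet(
        images, np.array(labels), [d.name for d in class_dirs], "all"
    )


def apportion(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n items; ties favour earlier
    fractions (train before val before test)."""
    quotas = [n * f for f in fractions]
    counts = [int(q) for q in quotas]
    order = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in order[: n - sum(counts)]:
        counts[i] += 1
    return counts


def split_dataset(
    dataset: LabeledImageSet,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Stratified random train/val/test split.

    Per class, indices are shuffled under ``seed`` and assigned by
    largest-remainder apportionment of the fractions, so the three parts
    are disjoint, their union is the input, and per-class proportions are
    within one item of the requested fractions.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    counts = dataset.class_counts()
    for k, c in enumerate(counts):
        if c < 3:
            raise ValueError(
                f"class {dataset.class_names[k]!r} has {c} items; need >= 3 to split"
            )
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for k in range(dataset.num_classes):
        idx = np.flatnonzero(dataset.labels == k)
        rng.shuffle(idx)
        n_tr, n_va, n_te = apportion(len(idx), fractions)
        parts[0].extend(idx[:n_tr])
        parts[1].extend(idx[n_tr : n_tr + n_va])
        parts[2].extend(idx[n_tr + n_va :])
    tags = ("train", "val", "test")
    return tuple(
        dataset.subset(np.array(sorted(p), dtype=np.int64), tag)
        for p, tag in zip(parts, tags)
    )


@dataclass
class AugmentConfig:
    """Training-time augmentation: random resized crop, flips, rotation,
    then resize to the network input size (224 in the study protocol)."""

    crop_scale: tuple[float, float] = (0.7, 1.0)
    crop_ratio: tuple[float, float] = (3.0 / 4.0, 4.0 / 3.0)
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    rotation_deg: float = 30.0
    out_size: int = 224


class Augmenter:
    """Seeded augmentation pipeline; a callable image -> image transform.

    Two augmenters built with the same seed produce identical outputs for
    identical call sequences.  Labels are untouched by construction.  With
    crop scale and ratio pinned to (1, 1), flip probabilities 0 and rotation
    0 the pipeline degenerates to a plain resize.
    """

    def __init__(self, seed: int = 0, cfg: AugmentConfig | None = None):
        self.cfg = cfg or AugmentConfig()
        self.rng = np.random.default_rng(seed)

    def _sample_crop(self, h: int, w: int) -> tuple[int, int, int, int]:
        cfg = self.cfg
        area = self.rng.uniform(*cfg.crop_scale) * h * w
        ratio = self.rng.uniform(*cfg.crop_ratio)
        cw = min(int(round(np.sqrt(area * ratio))), w)
        ch = min(int(round(np.sqrt(area / ratio))), h)
        cw, ch = max(cw, 1), max(ch, 1)
        top = int(self.rng.integers(0, h - ch + 1))
        left = int(self.rng.integers(0, w - cw + 1))
        return top, left, ch, cw

    def __call__(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("augmentation expects an RGB (H, W, 3) image")
        h, w = image.shape[:2]
        cfg = self.cfg
        top, left, ch, cw = self._sample_crop(h, w)
        im = Image.fromarray(image[top : top + ch, left : left + cw])
        if self.rng.random() < cfg.p_hflip:
            im = im.transpose(Image.FLIP_LEFT_RIGHT)
        if self.rng.random() < cfg.p_vflip:
            im = im.transpose(Image.FLIP_TOP_BOTTOM)
        if cfg.rotation_deg > 0:
            angle = float(self.rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
            im = im.rotate(angle, resample=Image.BILINEAR)
        im = im.resize((cfg.out_size, cfg.out_size), Image.BILINEAR)
        return np.asarray(im)


def augmentation_pipeline(seed: int = 0, cfg: AugmentConfig | None = None) -> Augmenter:
    """Build the study's training-time image transform (seeded)."""
    return Augmenter(seed, cfg)


def resize_images(images: list[np.ndarray], size: int) -> list[np.ndarray]:
    """Plain bilinear resize of every image to size x size (no augmentation)."""
    out = []
    for img in images:
        if img.shape[0] == size and img.shape[1] == size:
            out.append(img)
        else:
            out.append(
                np.asarray(Image.fromarray(img).resize((size, size), Image.BILINEAR))
            )
    return out


def to_network_input(images: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Stack 8-bit HxWx3 images into a float32 (N, 3, H, W) batch in [-1, 1]."""
    arr = np.stack([np.asarray(im) for im in images]).astype(np.float32)
    arr = arr / 127.5 - 1.0
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))
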
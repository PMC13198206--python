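"""Forward simulator of H&E-like tiles with known ground truth.

Tiles are rendered in concentration space — nuclei-like Gaussian blobs in
the Hematoxylin channel, a smooth cytoplasm-like Eosin field, optional
necrosis patches — and converted to RGB through the Beer-Lambert law using
per-slide drifted stain vectors, mimicking cross-slide stain variation.
The generator records ground-truth bases and hidden labels so every
downstream component can be validated against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .stainsep import RGBTile, RUIFROK_E_OD, RUIFROK_H_OD

__all__ = [
    "SlideSpec",
    "ClassTextureSpec",
    "DatasetManifest",
    "SyntheticDataset",
    "default_textures",
    "make_slide_spec",
    "render_tile",
    "sample_od_pixels",
    "generate_dataset",
    "load_dataset",
]

SPLITS = ("train_labeled", "train_unlabeled", "val", "test")


@dataclass(frozen=True)
class SlideSpec:
    """Ground-truth per-slide stain geometry, brightness and morphology.

    ``density_factor`` and ``amplitude_factor`` are slide-level
    morphological confounds (section thickness, fixation): they scale the
    class textures and — unlike stain-vector drift — survive stain
    separation, so they stress generalization across slides.
    """

    slide_id: str
    v_h: np.ndarray
    v_e: np.ndarray
    brightness_factor: float = 1.0
    density_factor: float = 1.0
    amplitude_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("v_h", "v_e"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v / np.linalg.norm(v))
        if not (0.7 <= self.brightness_factor <= 1.3):
            raise ValueError("brightness_factor outside [0.7, 1.3]")


@dataclass(frozen=True)
class ClassTextureSpec:
    """Class-conditional texture parameters for tile rendering."""

    class_id: str
    nuclei_density: float  # expected blob count per 96x96 tile
    nuclei_radius_range: tuple[float, float]
    h_amplitude_range: tuple[float, float]
    e_amplitude_range: tuple[float, float]
    necrosis_flag: bool = False

    def __post_init__(self) -> None:
        if self.nuclei_density < 0:
            raise ValueError("nuclei_density must be >= 0")
        for r in (self.h_amplitude_range, self.e_amplitude_range):
            if not (0 <= r[0] <= r[1] <= 1.5):
                raise ValueError("amplitude ranges must lie within [0, 1.5]")


def default_textures() -> list[ClassTextureSpec]:
    """Three-class texture set: class signal lives in both H morphology
    (nuclei density/size) and E level, so each view is informative."""
    return [
        ClassTextureSpec("benign", nuclei_density=14,
                         nuclei_radius_range=(2.0, 4.0),
                         h_amplitude_range=(0.40, 0.80),
                         e_amplitude_range=(0.22, 0.42)),
        ClassTextureSpec("cancer", nuclei_density=28,
                         nuclei_radius_range=(2.5, 5.0),
                         h_amplitude_range=(0.50, 0.90),
                         e_amplitude_range=(0.28, 0.48)),
        ClassTextureSpec("necrosis", nuclei_density=6,
                         nuclei_radius_range=(1.5, 3.0),
                         h_amplitude_range=(0.15, 0.40),
                         e_amplitude_range=(0.40, 0.65),
                         necrosis_flag=True),
    ]


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def make_slide_spec(slide_id: str, rng: np.random.Generator,
                    drift_deg: float = 8.0,
                    brightness_range: tuple[float, float] = (0.95, 1.05),
                    density_range: tuple[float, float] = (0.65, 1.55),
                    amplitude_range: tuple[float, float] = (0.85, 1.18),
                    seed: int | None = None) -> SlideSpec:
    """Draw a slide with stain vectors drifted from the canonical pair.

    Each stain vector rotates independently within the canonical stain plane
    (changing the stain angles), and the whole frame receives a small shared
    out-of-plane rotation.
    """
    v_h, v_e = RUIFROK_H_OD.copy(), RUIFROK_E_OD.copy()
    normal = np.cross(v_h, v_e)
    dh, de = np.deg2rad(rng.uniform(-drift_deg, drift_deg, size=2))
    v_h = _rotation_matrix(normal, dh) @ v_h
    v_e = _rotation_matrix(normal, de) @ v_e
    tilt_axis = rng.standard_normal(3)
    tilt = np.deg2rad(rng.uniform(-drift_deg / 2, drift_deg / 2))
    rot = _rotation_matrix(tilt_axis, tilt)
    v_h, v_e = rot @ v_h, rot @ v_e
    # keep vectors in the physical (non-negative OD) octant
    v_h, v_e = np.abs(v_h), np.abs(v_e)
    return SlideSpec(
        slide_id=slide_id,
        v_h=v_h,
        v_e=v_e,
        brightness_factor=float(rng.uniform(*brightness_range)),
        density_factor=float(rng.uniform(*density_range)),
        amplitude_factor=float(rng.uniform(*amplitude_range)),
        seed=int(seed if seed is not None else rng.integers(0, 2**31 - 1)),
    )


def _concentration_fields(texture: ClassTextureSpec, size: int,
                          rng: np.random.Generator,
                          density_factor: float = 1.0,
                          amplitude_factor: float = 1.0):
    """Draw ground-truth (alpha_H, alpha_E) fields for one tile."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    scale = (size / 96.0) ** 2

    # Hematoxylin: faint background plus nuclei-like Gaussian blobs.
    alpha_h = np.full((size, size), rng.uniform(0.005, 0.02))
    nuclei = np.zeros((size, size))
    n_blobs = rng.poisson(texture.nuclei_density * scale * density_factor)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, size, size=2)
        radius = rng.uniform(*texture.nuclei_radius_range) * (size / 96.0)
        amp = rng.uniform(*texture.h_amplitude_range) * amplitude_factor
        nuclei += amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2)
                                 / (2 * radius**2)))
    nuclei = np.minimum(nuclei, 1.4)
    alpha_h = alpha_h + nuclei

    # Eosin: smooth cytoplasm-like field, displaced by dense chromatin so
    # nucleus cores stay close to pure Hematoxylin.
    field = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 8)
    lo, hi = field.min(), field.max()
    field = (field - lo) / (hi - lo) if hi > lo else np.zeros_like(field)
    e_level = rng.uniform(*texture.e_amplitude_range) * amplitude_factor
    alpha_e = e_level * (0.7 + 0.6 * field)
    # dense chromatin displaces cytoplasm: suppression saturates per pixel,
    # leaving nucleus cores nearly pure Hematoxylin
    alpha_e = alpha_e * (1.0 - 0.97 * np.clip(nuclei / 0.4, 0.0, 1.0))

    if texture.necrosis_flag:
        n_patches = rng.integers(1, 4)
        mask = np.zeros((size, size))
        for _ in range(n_patches):
            cy, cx = rng.uniform(0, size, size=2)
            radius = rng.uniform(size / 4.5, size / 2.8)
            mask = np.maximum(
                mask,
                np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * radius**2))),
            )
        alpha_h = alpha_h * (1.0 - 0.75 * mask)
        alpha_e = alpha_e * (1.0 - 0.3 * mask) + 0.25 * mask

    return np.clip(alpha_h, 0.0, 1.5), np.clip(alpha_e, 0.0, 1.5)


def render_tile(slide: SlideSpec, texture: ClassTextureSpec, size: int = 96,
                noise_sd: float = 0.01, seed: int = 0,
                background_intensity: float = 255.0):
    """Render one tile; returns ``(RGBTile, alpha_H, alpha_E)`` ground truth.

    OD is the Beer-Lambert mixture ``alpha_H*V_H + alpha_E*V_E`` plus
    isotropic residual noise; RGB applies the slide's brightness factor to
    the incident intensity and quantizes to 8 bits.
    """
    if size < 32:
        raise ValueError("tile size must be >= 32")
    rng = np.random.default_rng(seed)
    alpha_h, alpha_e = _concentration_fields(
        texture, size, rng,
        density_factor=slide.density_factor,
        amplitude_factor=slide.amplitude_factor,
    )
    od = (alpha_h[..., None] * slide.v_h + alpha_e[..., None] * slide.v_e)
    if noise_sd > 0:
        od = od + noise_sd * rng.standard_normal(od.shape)
    od = np.maximum(od, 0.0)
    intensity = slide.brightness_factor * background_intensity * 10.0 ** (-od)
    pixels = np.clip(np.rint(intensity), 0, background_intensity).astype(np.int64)
    tile = RGBTile(pixels, background_intensity, slide_id=slide.slide_id)
    return tile, alpha_h, alpha_e


def random_stain_pair(rng: np.random.Generator,
                      theta_h_range: tuple[float, float] = (-60.0, -10.0),
                      theta_e_range: tuple[float, float] = (10.0, 60.0),
                      max_tries: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Draw a random physically valid ground-truth stain pair.

    Angles (degrees) are measured in a randomly tilted stain plane from its
    central axis; vectors are rejected until both land in the non-negative
    OD octant, as physical absorbance requires.
    """
    base_x = RUIFROK_H_OD + RUIFROK_E_OD
    base_x = base_x / np.linalg.norm(base_x)
    base_y = RUIFROK_E_OD - np.dot(RUIFROK_E_OD, base_x) * base_x
    base_y = base_y / np.linalg.norm(base_y)
    for _ in range(max_tries):
        rot = _rotation_matrix(rng.standard_normal(3),
                               np.deg2rad(rng.uniform(-15, 15)))
        v_x, v_y = rot @ base_x, rot @ base_y
        th = np.deg2rad(rng.uniform(*theta_h_range))
        te = np.deg2rad(rng.uniform(*theta_e_range))
        v_h = np.cos(th) * v_x + np.sin(th) * v_y
        v_e = np.cos(te) * v_x + np.sin(te) * v_y
        if v_h.min() >= 0 and v_e.min() >= 0:
            return v_h, v_e
    raise RuntimeError("could not sample a physical stain pair")


def sample_od_pixels(v_h: np.ndarray, v_e: np.ndarray, n: int,
                     rng: np.random.Generator, noise_sd: float = 0.0,
                     pure_fraction: float = 0.3) -> np.ndarray:
    """Sample OD pixels from a Beer-Lambert mixture with known stain vectors.

    A fraction of pixels is nearly pure in each stain (nucleus cores /
    stroma), the rest mixed — mirroring real tissue, where near-pure pixels
    are what make robust extreme-angle stain estimation identifiable.
    """
    v_h = np.asarray(v_h) / np.linalg.norm(v_h)
    v_e = np.asarray(v_e) / np.linalg.norm(v_e)
    kind = rng.choice(3, size=n, p=[pure_fraction, pure_fraction,
                                    1 - 2 * pure_fraction])
    alpha_h = np.where(kind == 0, rng.uniform(0.3, 1.2, n),
                       np.where(kind == 1, rng.uniform(0.0, 0.02, n),
                                rng.uniform(0.05, 1.0, n)))
    alpha_e = np.where(kind == 1, rng.uniform(0.3, 1.2, n),
                       np.where(kind == 0, rng.uniform(0.0, 0.02, n),
                                rng.uniform(0.05, 1.0, n)))
    od = alpha_h[:, None] * v_h + alpha_e[:, None] * v_e
    if noise_sd > 0:
        od = od + noise_sd * rng.standard_normal(od.shape)
    return np.maximum(od, 0.0)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


@dataclass
class DatasetManifest:
    """Tile bookkeeping: path, slide, optional label, split."""

    frame: pd.DataFrame
    class_names: list[str]

    def __post_init__(self) -> None:
        required = {"tile_path", "slide_id", "label", "split"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns {sorted(missing)}")
        labeled = self.frame["label"].fillna("") != ""
        bad = set(self.frame.loc[labeled, "label"]) - set(self.class_names)
        if bad:
            raise ValueError(f"labels outside class_names: {sorted(bad)}")

    def rows(self, split: str) -> pd.DataFrame:
        return self.frame[self.frame["split"] == split].reset_index(drop=True)

    def save(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def load(cls, path, class_names: Sequence[str] | None = None
             ) -> "DatasetManifest":
        frame = pd.read_csv(path, keep_default_na=False)
        if class_names is None:
            labels = frame["label"][frame["label"] != ""]
            class_names = sorted(labels.unique())
        return cls(frame, list(class_names))


class InMemoryTiles:
    """Tile store backed by a dict (used by the in-memory simulator path)."""

    def __init__(self, tiles: dict[str, RGBTile] | None = None):
        self._tiles = tiles or {}

    def put(self, path: str, tile: RGBTile) -> None:
        self._tiles[path] = tile

    def get(self, path: str) -> RGBTile:
        return self._tiles[path]


class DiskTiles:
    """Tile store reading PNG/TIFF files relative to a root directory."""

    def __init__(self, root, background_intensity: float = 255.0,
                 slide_lookup: Mapping[str, str] | None = None):
        self.root = Path(root)
        self.background_intensity = background_intensity
        self.slide_lookup = dict(slide_lookup or {})

    def get(self, path: str) -> RGBTile:
        full = self.root / path
        arr = np.asarray(Image.open(full).convert("RGB"), dtype=np.int64)
        return RGBTile(arr, self.background_intensity,
                       slide_id=self.slide_lookup.get(path, ""))


@dataclass
class SyntheticDataset:
    manifest: DatasetManifest
    tiles: InMemoryTiles
    slides: dict[str, SlideSpec]
    hidden_labels: dict[str, str] = field(default_factory=dict)


def _partition_slides(slide_ids: list[str], rng: np.random.Generator
                      ) -> dict[str, list[str]]:
    if len(slide_ids) < 3:
        raise ValueError("need at least 3 slides for disjoint train/val/test")
    ids = list(slide_ids)
    rng.shuffle(ids)
    n = len(ids)
    n_test = max(1, n // 5)
    n_val = max(1, n // 5)
    return {
        "test": ids[:n_test],
        "val": ids[n_test : n_test + n_val],
        "train": ids[n_test + n_val :],
    }


def generate_dataset(
    n_slides: int = 6,
    classes: Sequence[ClassTextureSpec] | None = None,
    n_labeled_per_class: int = 30,
    n_unlabeled: int = 300,
    n_val_per_class: int = 20,
    n_test_per_class: int = 20,
    tile_size: int = 96,
    noise_sd: float = 0.01,
    drift_deg: float = 8.0,
    n_labeled_slides: int | None = None,
    seed: int = 0,
    out_dir=None,
) -> SyntheticDataset:
    """Generate a full synthetic dataset with slide-disjoint splits.

    Validation/test tiles come only from held-out slides; unlabeled training
    tiles carry hidden true labels recorded in a sidecar for diagnostics.
    ``n_labeled_slides`` restricts labeled tiles to that many training
    slides while unlabeled tiles still come from all training slides —
    mirroring annotation of a subset of slides with the rest contributing
    only unlabeled tiles.  When ``out_dir`` is given, tiles are written as
    PNG along with ``manifest.csv`` and ``truth.json``.
    """
    classes = list(classes) if classes is not None else default_textures()
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for count in (n_labeled_per_class, n_unlabeled, n_val_per_class,
                  n_test_per_class):
        if count < 0:
            raise ValueError("tile counts must be >= 0")
    rng = np.random.default_rng(seed)
    slides = {
        f"slide_{i:02d}": make_slide_spec(f"slide_{i:02d}", rng,
                                          drift_deg=drift_deg)
        for i in range(n_slides)
    }
    parts = _partition_slides(list(slides), rng)
    by_class = {t.class_id: t for t in classes}
    class_names = [t.class_id for t in classes]

    store = InMemoryTiles()
    hidden: dict[str, str] = {}
    rows = []
    counter = 0

    def emit(split: str, slide_pool: list[str], texture: ClassTextureSpec,
             label: str) -> None:
        nonlocal counter
        slide_id = slide_pool[int(rng.integers(len(slide_pool)))]
        tile_seed = int(rng.integers(0, 2**31 - 1))
        tile, _, _ = render_tile(slides[slide_id], texture, size=tile_size,
                                 noise_sd=noise_sd, seed=tile_seed)
        path = f"tiles/{split}/tile_{counter:05d}.png"
        counter += 1
        store.put(path, tile)
        rows.append({"tile_path": path, "slide_id": slide_id,
                     "label": label, "split": split})
        if label == "":
            hidden[path] = texture.class_id

    labeled_slides = parts["train"]
    if n_labeled_slides is not None:
        if not 1 <= n_labeled_slides <= len(parts["train"]):
            raise ValueError(
                f"n_labeled_slides must be in [1, {len(parts['train'])}]"
            )
        labeled_slides = parts["train"][:n_labeled_slides]
    for texture in classes:
        for _ in range(n_labeled_per_class):
            emit("train_labeled", labeled_slides, texture, texture.class_id)
    for _ in range(n_unlabeled):
        texture = by_class[class_names[int(rng.integers(len(class_names)))]]
        emit("train_unlabeled", parts["train"], texture, "")
    for texture in classes:
        for _ in range(n_val_per_class):
            emit("val", parts["val"], texture, texture.class_id)
        for _ in range(n_test_per_class):
            emit("test", parts["test"], texture, texture.class_id)

    manifest = DatasetManifest(pd.DataFrame(rows), class_names)
    dataset = SyntheticDataset(manifest, store, slides, hidden)
    if out_dir is not None:
        _write_dataset(dataset, out_dir)
    return dataset


def _write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path, tile in dataset.tiles._tiles.items():
        full = out / path
        full.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(tile.pixels.astype(np.uint8)).save(full)
    dataset.manifest.save(out / "manifest.csv")
    truth = {
        "class_names": dataset.manifest.class_names,
        "slides": {
            sid: {
                "v_h": s.v_h.tolist(),
                "v_e": s.v_e.tolist(),
                "brightness_factor": s.brightness_factor,
                "seed": s.seed,
            }
            for sid, s in dataset.slides.items()
        },
        "hidden_labels": dataset.hidden_labels,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))


def load_dataset(root) -> tuple[DatasetManifest, DiskTiles, dict]:
    """Load a previously written synthetic dataset directory."""
    root = Path(root)
    truth = json.loads((root / "truth.json").read_text()) \
        if (root / "truth.json").exists() else {}
    manifest = DatasetManifest.load(root / "manifest.csv",
                                    truth.get("class_names"))
    lookup = dict(zip(manifest.frame["tile_path"], manifest.frame["slide_id"]))
    return manifest, DiskTiles(root, slide_lookup=lookup), truth
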
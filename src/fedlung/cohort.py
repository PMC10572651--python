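"""Synthetic CT-like nodule slices and Pa/Pd feature extraction.

Generates grayscale 2-D slices in three classes — *normal* (background
parenchyma only, no lesion), *benign* (one compact, smooth-boundary nodule)
and *malignant* (one larger, brighter nodule with a spiculated boundary) —
and extracts the eight-dimensional feature vector used by the classifier:
four "physical" attributes (density, mass, orientation, weight) and four
"digital" attributes (pixel ratio, growth pattern, pixel intensity,
expansion density), all computed from the slice's Region of Interest (RoI).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

CLASS_LABELS: tuple[str, str, str] = ("normal", "benign", "malignant")

FEATURE_NAMES: tuple[str, ...] = (
    "density",
    "mass",
    "orientation",
    "weight",
    "pixel_ratio",
    "growth_pattern",
    "pixel_intensity",
    "expansion_density",
)

#: indices of the physical (Pa) and digital (Pd) attribute groups inside the
#: concatenated feature vector Pa ⊕ Pd
PA_INDICES: tuple[int, ...] = (0, 1, 2, 3)
PD_INDICES: tuple[int, ...] = (4, 5, 6, 7)

#: fixed foreground threshold for RoI detection; background is a truncated
#: Gaussian with mean 0.2, sd 0.05, clipped to [0, 0.40], so no background
#: pixel can cross the threshold and normal slices have an exactly empty RoI
FOREGROUND_THRESHOLD = 0.45
_BG_MEAN = 0.2
_BG_SD = 0.05
_BG_CLIP = 0.40


@dataclass(frozen=True)
class SliceImage:
    """One grayscale slice; intensities in [0, 1]."""

    pixels: np.ndarray
    slice_thickness_mm: float = 1.25
    case_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError("pixels must be a 2-D grid with H, W >= 16")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class PhysicalAttributes:
    """Pa: density, mass, orientation, weight — all zero for an empty RoI."""

    density: float = 0.0
    mass: float = 0.0
    orientation: float = 0.0
    weight: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.density, self.mass, self.orientation, self.weight], dtype=float
        )


@dataclass(frozen=True)
class DigitalAttributes:
    """Pd: pixel_ratio, growth_pattern, pixel_intensity, expansion_density."""

    pixel_ratio: float = 0.0
    growth_pattern: float = 0.0
    pixel_intensity: float = 0.0
    expansion_density: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.pixel_ratio,
                self.growth_pattern,
                self.pixel_intensity,
                self.expansion_density,
            ],
            dtype=float,
        )


@dataclass(frozen=True)
class LabeledCase:
    image: SliceImage
    label: str
    features: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        f = np.asarray(self.features, dtype=float)
        if f.shape != (8,) or not np.all(np.isfinite(f)):
            raise ValueError("features must be 8 finite values")
        object.__setattr__(self, "features", f)


@dataclass(frozen=True)
class Cohort:
    cases: tuple[LabeledCase, ...]
    seed: int
    class_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = {lab: 0 for lab in CLASS_LABELS}
        ids = set()
        for c in self.cases:
            counts[c.label] += 1
            ids.add(c.image.case_id)
        if len(ids) != len(self.cases):
            raise ValueError("case_ids must be unique")
        object.__setattr__(self, "class_counts", counts)

    def __len__(self) -> int:
        return len(self.cases)

    def feature_matrix(self) -> np.ndarray:
        return np.stack([c.features for c in self.cases])

    def label_indices(self) -> np.ndarray:
        return np.array([CLASS_LABELS.index(c.label) for c in self.cases])


@dataclass(frozen=True)
class GeneratorParams:
    """Settings for the synthetic slice generator.

    Radii are in pixels; intensities in [0, 1]. The malignant boundary is
    spiculated: r(theta) = r0 * (1 + a * sum_k sin(k*theta + phi_k)) over the
    configured harmonics, giving an irregular, lobulated outline, while the
    benign boundary is a plain disk (amplitude 0).
    """

    image_size: int = 64
    benign_radius: tuple[float, float] = (3.0, 6.0)
    benign_intensity: float = 0.6
    benign_spiculation: float = 0.0
    malignant_radius: tuple[float, float] = (5.0, 9.0)
    malignant_intensity: float = 0.8
    malignant_spiculation: float = 0.35
    spiculation_harmonics: tuple[int, ...] = (3, 5, 7)
    edge_blur_sd: float = 1.0
    slice_thickness_mm: float = 1.25

    def __post_init__(self) -> None:
        for lo, hi in (self.benign_radius, self.malignant_radius):
            if not (0 < lo <= hi):
                raise ValueError("radius ranges must be ordered and positive")
        if self.benign_spiculation < 0 or self.malignant_spiculation < 0:
            raise ValueError("spiculation amplitudes must be >= 0")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")

    def max_extent(self, label: str) -> float:
        """Worst-case lesion radius for placement/feasibility checks."""
        if label == "benign":
            r, a = self.benign_radius[1], self.benign_spiculation
        else:
            r, a = self.malignant_radius[1], self.malignant_spiculation
        return r * (1.0 + a * len(self.spiculation_harmonics))


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(_BG_MEAN, _BG_SD, size=(size, size))
    return np.clip(noise, 0.0, _BG_CLIP)


def _nodule_mask(
    size: int,
    center: tuple[float, float],
    r0: float,
    amplitude: float,
    harmonics: Sequence[int],
    phases: np.ndarray,
) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - center[0]
    dx = xx - center[1]
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r = r0 * np.ones_like(dist)
    if amplitude > 0:
        mod = np.zeros_like(theta)
        for k, phi in zip(harmonics, phases):
            mod += np.sin(k * theta + phi)
        r = r0 * np.clip(1.0 + amplitude * mod, 0.15, None)
    return dist <= r


def generate_case(
    label: str, gen_params: GeneratorParams, rng: np.random.Generator
) -> LabeledCase:
    """Generate one labeled slice; deterministic given (label, params, rng state).

    normal slices carry only background noise (empty RoI by construction);
    benign slices one smooth disk; malignant slices one brighter, larger,
    spiculated nodule.
    """
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown label {label!r}")
    size = gen_params.image_size
    img = _background(size, rng)
    if label != "normal":
        margin = gen_params.max_extent(label) + 2.0
        if 2 * margin >= size:
            raise ValueError("generator params produce an RoI larger than the image")
        if label == "benign":
            r0 = rng.uniform(*gen_params.benign_radius)
            amp = gen_params.benign_spiculation
            core = gen_params.benign_intensity
        else:
            r0 = rng.uniform(*gen_params.malignant_radius)
            amp = gen_params.malignant_spiculation
            core = gen_params.malignant_intensity
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        phases = rng.uniform(0, 2 * math.pi, size=len(gen_params.spiculation_harmonics))
        mask = _nodule_mask(
            size, (cy, cx), r0, amp, gen_params.spiculation_harmonics, phases
        )
        lesion = np.where(mask, core, 0.0)
        if gen_params.edge_blur_sd > 0:
            lesion = ndi.gaussian_filter(lesion, gen_params.edge_blur_sd)
        img = np.clip(np.maximum(img, lesion), 0.0, 1.0)
    image = SliceImage(
        pixels=img,
        slice_thickness_mm=gen_params.slice_thickness_mm,
        case_id="",
    )
    return LabeledCase(image=image, label=label, features=extract_features(image))


def largest_remainder_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Integer class counts by largest-remainder rounding; ties in label order."""
    props = np.asarray(proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    raw = n * props
    counts = np.floor(raw).astype(int)
    frac = raw - counts
    # stable sort descending on fraction keeps earlier labels first on ties
    order = np.argsort(-frac, kind="stable")
    for i in range(n - counts.sum()):
        counts[order[i]] += 1
    return counts.tolist()


def generate_cohort(
    n_cases: int,
    class_mix: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    gen_params: GeneratorParams | None = None,
    seed: int = 0,
) -> Cohort:
    """Generate a labeled cohort with exact largest-remainder class counts.

    Reproducible bit-for-bit: each case has its own random stream derived
    from (seed, case index), and the final case order is a seeded shuffle.
    """
    if n_cases < 3:
        raise ValueError("n_cases must be >= 3")
    gen_params = gen_params or GeneratorParams()
    counts = largest_remainder_counts(n_cases, class_mix)
    labels = [lab for lab, c in zip(CLASS_LABELS, counts) for _ in range(c)]
    cases = []
    for idx, lab in enumerate(labels):
        rng = np.random.default_rng(np.random.SeedSequence((seed, idx)))
        case = generate_case(lab, gen_params, rng)
        image = dataclasses.replace(case.image, case_id=f"case{idx:05d}")
        cases.append(LabeledCase(image=image, label=lab, features=case.features))
    order = np.random.default_rng(np.random.SeedSequence((seed, 0xA1))).permutation(
        n_cases
    )
    return Cohort(cases=tuple(cases[i] for i in order), seed=seed)


def _orientation_from_mask(mask: np.ndarray) -> float:
    """Principal-axis angle (x-axis convention, radians in [-pi/2, pi/2]).

    Degenerate (rotationally symmetric) second moments map to 0.
    """
    ys, xs = np.nonzero(mask)
    x = xs - xs.mean()
    y = ys - ys.mean()
    mu20 = float(np.sum(x * x))
    mu02 = float(np.sum(y * y))
    mu11 = float(np.sum(x * y))
    a, b = mu20 - mu02, 2.0 * mu11
    scale = mu20 + mu02
    if scale == 0 or math.hypot(a, b) < 1e-9 * scale:
        return 0.0
    theta = 0.5 * math.atan2(b, a)
    # image rows grow downward; negate so angles follow the usual y-up sense
    theta = -theta
    if theta > math.pi / 2:
        theta -= math.pi
    elif theta <= -math.pi / 2:
        theta += math.pi
    return theta


def _expansion_density(pixels: np.ndarray, mask: np.ndarray) -> float:
    """Mean |radial intensity derivative| over a 2-px band at the RoI boundary."""
    band = ndi.binary_dilation(mask) & ~ndi.binary_erosion(mask)
    if not band.any():
        return 0.0
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    gy, gx = np.gradient(pixels)
    by, bx = np.nonzero(band)
    uy = by - cy
    ux = bx - cx
    norm = np.hypot(uy, ux)
    norm[norm == 0] = 1.0
    radial = (gy[by, bx] * uy + gx[by, bx] * ux) / norm
    return float(np.mean(np.abs(radial)))


def extract_features(image: SliceImage) -> np.ndarray:
    """Extract the 8-vector Pa ⊕ Pd from a slice.

    The RoI is the largest connected component of pixels strictly above the
    foreground threshold; if none exists all eight features are zero.
    Pure function: repeated calls agree exactly.
    """
    px = image.pixels
    if not np.all(np.isfinite(px)):
        raise ValueError("non-finite pixel values")
    fg = px > FOREGROUND_THRESHOLD
    if not fg.any():
        return np.zeros(8)
    labels_img = measure.label(fg, connectivity=2)
    sizes = np.bincount(labels_img.ravel())
    sizes[0] = 0
    roi = labels_img == sizes.argmax()
    area = float(roi.sum())
    total = float(px.size)
    density = float(px[roi].mean())
    mass = density * area
    orientation = _orientation_from_mask(roi)
    weight = (area / total) * density
    pixel_ratio = area / total
    perimeter = float(measure.perimeter_crofton(roi, directions=4))
    growth_pattern = max(1.0, perimeter**2 / (4.0 * math.pi * area))
    pixel_intensity = float(px[roi].max())
    expansion = _expansion_density(px, roi)
    pa = PhysicalAttributes(density, mass, orientation, weight)
    pd_ = DigitalAttributes(pixel_ratio, growth_pattern, pixel_intensity, expansion)
    return np.concatenate([pa.as_array(), pd_.as_array()])


def split_cohort(
    cohort: Cohort, train_fraction: float, seed: int
) -> tuple[tuple[LabeledCase, ...], tuple[LabeledCase, ...]]:
    """Stratified train/test split; per-class train count = round(f * count).

    Rounding is half-up, clamped so both subsets keep at least one case of
    every class. Disjoint, union-preserving and deterministic per seed.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA2)))
    train: list[LabeledCase] = []
    test: list[LabeledCase] = []
    for lab in CLASS_LABELS:
        members = [c for c in cohort.cases if c.label == lab]
        if len(members) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 cases; cannot stratify")
        k = int(math.floor(train_fraction * len(members) + 0.5))
        k = min(max(k, 1), len(members) - 1)
        order = rng.permutation(len(members))
        train.extend(members[i] for i in order[:k])
        test.extend(members[i] for i in order[k:])
    return tuple(train), tuple(test)


# ---------------------------------------------------------------------------
# On-disk interchange: 8-bit grayscale PNGs plus CSV manifests
# ---------------------------------------------------------------------------


def save_image_png(image: SliceImage, path) -> None:
    """Write as 8-bit grayscale; intensity mapped to 0-255, round-half-up."""
    from PIL import Image as PILImage

    arr = np.floor(image.pixels * 255.0 + 0.5).clip(0, 255).astype(np.uint8)
    PILImage.fromarray(arr, mode="L").save(path)


def load_image_png(path, slice_thickness_mm: float = 1.25, case_id: str = "") -> SliceImage:
    from PIL import Image as PILImage

    arr = np.asarray(PILImage.open(path).convert("L"), dtype=float) / 255.0
    return SliceImage(pixels=arr, slice_thickness_mm=slice_thickness_mm, case_id=case_id)


def write_cohort(
    cohort: Cohort,
    out_dir,
    split_map: dict | None = None,
    client_map: dict | None = None,
) -> None:
    """Write PNGs plus manifest.csv (case_id,label,split,client_id,px_file)
    and features.csv with the 8 named feature columns (UTF-8, LF endings)."""
    import pandas as _pd
    from pathlib import Path as _Path

    out = _Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    split_map = split_map or {}
    client_map = client_map or {}
    manifest, feats = [], []
    for case in cohort.cases:
        cid = case.image.case_id
        px_file = f"images/{cid}.png"
        save_image_png(case.image, out / px_file)
        manifest.append(
            {
                "case_id": cid,
                "label": case.label,
                "split": split_map.get(cid, ""),
                "client_id": client_map.get(cid, ""),
                "px_file": px_file,
            }
        )
        feats.append({"case_id": cid, **dict(zip(FEATURE_NAMES, case.features))})
    _pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False, lineterminator="\n")
    _pd.DataFrame(feats).to_csv(out / "features.csv", index=False, lineterminator="\n")
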
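"""Synthetic phantom-image generator for the six diagnostic classes.

The generator renders statistical look-alikes of reconstructed microwave
brain images: a roughly circular head region on a dark background, colored
through a heat-map palette, containing 0-2 bright tumour blobs.  Class
identity is encoded exactly the way the diagnostic classes are defined:
the blob count (0, 1 or 2) and each blob's shape regularity.  Benign
tumours are near-circular ellipses; malignant tumours are irregular
star-shaped polygons whose measured circularity 4*pi*A/P^2 falls below a
configurable ceiling.  The two shape families are separable by
construction: every generated benign blob measures at or above
``benign_circularity_min`` and every malignant blob below
``malignant_circularity_max``, with the first strictly greater than the
second.

This is not an electromagnetic model: no antenna physics or image
reconstruction is simulated, and the intensity statistics are plausible
rather than calibrated.  Its purpose is to make every pipeline stage
(loading, augmentation, fold planning, training, evaluation) testable at
desk scale with a task that is learnable by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as _draw_polygon
from skimage.measure import label as _cc_label, regionprops

from .data import LabeledImage
from .labels import CLASS_NAMES, ClassLabel

__all__ = [
    "PhantomParams",
    "TumorDescriptor",
    "GroundTruth",
    "HeatPalette",
    "PlacementError",
    "generate_image",
    "generate_arrays",
    "generate_dataset",
    "rule_based_label",
    "measure_circularity",
]


class PlacementError(RuntimeError):
    """A tumour could not be placed inside the head after bounded retries."""


# spikes of a malignant blob may reach this multiple of its nominal radius
MAX_SPIKE = 1.5


class HeatPalette:
    """Piecewise-linear scalar-to-RGB map with monotone luminance.

    The default stops run dark navy -> dark red -> orange -> yellow ->
    near-white, resembling the thermal rendering of reconstructed
    microwave images while keeping luminance strictly increasing, so a
    single luminance threshold recovers a scalar-intensity threshold.
    """

    DEFAULT_STOPS = (
        (0.00, (0.01, 0.01, 0.12)),
        (0.35, (0.50, 0.08, 0.08)),
        (0.65, (0.95, 0.40, 0.05)),
        (0.85, (1.00, 0.80, 0.15)),
        (1.00, (1.00, 1.00, 0.85)),
    )

    def __init__(self, stops=DEFAULT_STOPS):
        self.t = np.array([s[0] for s in stops])
        self.rgb = np.array([s[1] for s in stops])

    def __call__(self, scalar: np.ndarray) -> np.ndarray:
        scalar = np.clip(scalar, 0.0, 1.0)
        return np.stack(
            [np.interp(scalar, self.t, self.rgb[:, c]) for c in range(3)], axis=-1
        )

    def luminance(self, t: float) -> float:
        r, g, b = self(np.asarray(t)).T
        return float(0.2126 * r + 0.7152 * g + 0.0722 * b)


@dataclass
class PhantomParams:
    """Generator controls; defaults define the standard study conditions."""

    image_size: int = 224
    head_radius_frac: tuple[float, float] = (0.38, 0.45)  # of image width
    background_noise_sd: float = 0.02
    tumor_radius_frac: tuple[float, float] = (0.04, 0.10)
    benign_circularity_min: float = 0.85
    malignant_circularity_max: float = 0.70
    background_intensity: float = 0.05
    head_intensity: float = 0.35
    tumor_intensity: tuple[float, float] = (0.78, 0.95)
    edge_sigma: float = 1.0
    detection_threshold: float = 0.60  # scalar level separating tumour from head
    palette: HeatPalette = field(default_factory=HeatPalette)
    seed: int = 0

    def __post_init__(self):
        if not self.benign_circularity_min > self.malignant_circularity_max:
            raise ValueError(
                "benign_circularity_min must exceed malignant_circularity_max "
                f"({self.benign_circularity_min} vs {self.malignant_circularity_max})"
            )
        if self.image_size < 48:
            # below ~48 px the 4.5 px blob-radius floor cannot coexist with
            # two-tumour placement inside the head disk
            raise ValueError(f"image_size must be >= 48, got {self.image_size}")


@dataclass
class TumorDescriptor:
    center: tuple[float, float]  # (row, col) in pixels
    radius: float  # equivalent radius sqrt(A / pi), pixels
    kind: str  # "benign" | "malignant"
    circularity: float


@dataclass
class GroundTruth:
    label: ClassLabel
    tumors: list[TumorDescriptor]


_KINDS = {
    ClassLabel.NT: (),
    ClassLabel.BT: ("benign",),
    ClassLabel.MT: ("malignant",),
    ClassLabel.BBT: ("benign", "benign"),
    ClassLabel.MMT: ("malignant", "malignant"),
    ClassLabel.BMT: ("benign", "malignant"),
}


def measure_circularity(mask: np.ndarray) -> float:
    """4*pi*Area / Perimeter^2 of the largest region of a binary mask."""
    props = regionprops(_cc_label(mask))
    if not props:
        return 0.0
    region = max(props, key=lambda r: r.area)
    perim = region.perimeter
    if perim == 0:
        return 0.0
    return float(4.0 * np.pi * region.area / perim**2)


def _star_mask(size, center, radius, ratio, angle, amplitude, rng_u):
    """Rasterize a radially perturbed ellipse as a filled polygon.

    amplitude = 0 gives a regular ellipse with the given axis ratio;
    rng_u is a fixed vector of U[-1, 1] radial perturbations so that
    amplitude sweeps deform one shape continuously.  Vertex radii are
    clipped to [0.3, 1.5] x radius (spikes out to at most MAX_SPIKE times
    the nominal radius, notches down to 0.3); tumour placement budgets for
    the full spike extent, so blobs stay inside the head.
    """
    theta = np.linspace(0, 2 * np.pi, rng_u.size, endpoint=False)
    r = radius * np.clip(1.0 + amplitude * rng_u, 0.3, MAX_SPIKE)
    r = np.maximum(r, 1.5)
    y = center[0] + r * ratio * np.sin(theta + angle)
    x = center[1] + r * np.cos(theta + angle)
    rr, cc = _draw_polygon(y, x, shape=(size, size))
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    return mask


def _make_tumor_mask(size, center, radius, kind, params, rng):
    """Binary tumour mask with shape regularity enforced by measurement.

    Benign: a regular ellipse (axis ratio 0.9-1.0); retried with a rounder
    ratio if the discretized circularity measures below the benign floor.
    Malignant: the perturbation amplitude of a star polygon is increased
    until the measured circularity drops below the malignant ceiling, so
    malignant shapes sit just under that ceiling.
    """
    if kind == "benign":
        angle = rng.uniform(0, 2 * np.pi)
        ratio = rng.uniform(0.9, 1.0)
        for _ in range(8):
            mask = _star_mask(size, center, radius, ratio, angle, 0.0, np.zeros(24))
            circ = measure_circularity(mask)
            if circ >= params.benign_circularity_min:
                return mask, circ
            ratio = min(1.0, ratio + 0.03)
            radius *= 1.05  # discretization noise shrinks at larger radii
        raise PlacementError(f"could not realize a benign blob with circularity >= "
                             f"{params.benign_circularity_min}")
    # the amplitude sweep saturates once every vertex hits the radial clip,
    # so unlucky perturbation draws are re-drawn rather than swept further
    for _ in range(12):
        angle = rng.uniform(0, 2 * np.pi)
        u = rng.uniform(-1.0, 1.0, size=rng.integers(10, 17))
        amplitude = 0.12
        for _ in range(12):
            mask = _star_mask(size, center, radius, 1.0, angle, amplitude, u)
            circ = measure_circularity(mask)
            if circ < params.malignant_circularity_max:
                return mask, circ
            amplitude *= 1.45
    raise PlacementError(f"could not realize a malignant blob with circularity < "
                         f"{params.malignant_circularity_max}")


def generate_image(label, params: PhantomParams | None = None, rng=None):
    """Render one labeled phantom image.

    Deterministic given (label, params, rng state); ``rng`` may be a seed
    or a Generator.  Returns (LabeledImage, GroundTruth).
    """
    label = ClassLabel(label)
    params = params or PhantomParams()
    rng = np.random.default_rng(rng)
    s = params.image_size

    # head disk: slightly anisotropic ellipse with a soft boundary
    head_r = rng.uniform(*params.head_radius_frac) * s
    cy = s / 2 + rng.uniform(-0.02, 0.02) * s
    cx = s / 2 + rng.uniform(-0.02, 0.02) * s
    ry = head_r
    rx = head_r * rng.uniform(0.92, 1.0)
    yy, xx = np.mgrid[0:s, 0:s]
    head = (((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2) <= 1.0
    soft_head = gaussian_filter(head.astype(float), 2.0)

    # low-level interior texture, clipped so no NT pixel strays past 3 sd
    noise = rng.normal(size=(s, s))
    noise = gaussian_filter(noise, 2.0)
    sd = noise.std()
    if sd > 0:
        noise = noise / sd * params.background_noise_sd
    noise = np.clip(noise, -2.9 * params.background_noise_sd,
                    2.9 * params.background_noise_sd)

    scalar = (params.background_intensity
              + (params.head_intensity - params.background_intensity) * soft_head
              + noise * head)

    # tumour placement inside the head with margins and mutual separation;
    # all centres are drawn jointly so a central first blob cannot wedge a
    # second one out of the admissible disk
    kinds = _KINDS[label]
    # shape irregularity only rasterizes above ~4-5 px equivalent radius, so
    # radii are floored at 4.5 px (binding only for images below ~112 px;
    # applied to both shape families so size never becomes a class cue)
    radii = [max(rng.uniform(*params.tumor_radius_frac) * s, 4.5) for _ in kinds]
    # malignant spikes may reach MAX_SPIKE x the nominal radius; budget for
    # that extent so every vertex stays inside the head disk
    extents = [
        MAX_SPIKE * r if k == "malignant" else 1.1 * r for k, r in zip(kinds, radii)
    ]
    centers: list[tuple[float, float]] = []
    for _ in range(2000):
        trial = []
        for extent in extents:
            rad_pos = rng.uniform(0, max(min(ry, rx) - extent - 0.05 * s, 1.0))
            ang = rng.uniform(0, 2 * np.pi)
            trial.append((cy + rad_pos * np.sin(ang), cx + rad_pos * np.cos(ang)))
        ok = all(
            np.hypot(trial[i][0] - trial[j][0], trial[i][1] - trial[j][1])
            >= 0.8 * (extents[i] + extents[j]) + 0.06 * s
            for i in range(len(trial))
            for j in range(i + 1, len(trial))
        )
        if ok:
            centers = trial
            break
    else:
        raise PlacementError(
            f"no admissible placement for {len(kinds)} tumours of radii "
            f"{[round(r, 1) for r in radii]}px"
        )
    tumors: list[TumorDescriptor] = []
    for kind, radius, (ty, tx) in zip(kinds, radii, centers):
        mask, circ = _make_tumor_mask(s, (ty, tx), radius, kind, params, rng)
        soft = gaussian_filter(mask.astype(float), params.edge_sigma)
        level = rng.uniform(*params.tumor_intensity)
        scalar = scalar * (1 - soft) + soft * level
        eq_radius = float(np.sqrt(mask.sum() / np.pi))
        tumors.append(TumorDescriptor((float(ty), float(tx)), eq_radius, kind, circ))

    rgb = params.palette(scalar)
    img = LabeledImage(rgb, label, f"synthetic/{label.name}")
    return img, GroundTruth(label, tumors)


def generate_arrays(n_per_class, params: PhantomParams | None = None, seed=None):
    """In-memory dataset: (images, labels, ground_truths).

    ``n_per_class`` is an int (same count per class) or a mapping
    class-name/ClassLabel -> count.  Per-image seeds are derived from
    ``seed`` (defaulting to params.seed), so the dataset is reproducible
    and any image is regenerable in isolation.
    """
    params = params or PhantomParams()
    seed = params.seed if seed is None else seed
    if isinstance(n_per_class, int):
        n_per_class = {c: n_per_class for c in ClassLabel}
    images, labels, truths = [], [], []
    for c in ClassLabel:
        count = n_per_class.get(c, n_per_class.get(c.name, 0))
        for i in range(count):
            img, gt = generate_image(c, params, rng=[seed, int(c), i])
            img.source_id = f"synthetic/{c.name}/{i:04d}"
            images.append(img)
            labels.append(c)
            truths.append(gt)
    return images, np.array(labels, dtype=int), truths


def generate_dataset(n_per_class, params: PhantomParams | None = None, out_dir="."):
    """Write PNG files into six class subfolders plus a JSON manifest.

    Returns the manifest path.  Total files written equals the sum of the
    requested counts; the folder layout matches the loader's expectation.
    """
    params = params or PhantomParams()
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out_dir}: {e}") from e
    images, labels, truths = generate_arrays(n_per_class, params)
    manifest = []
    for name in CLASS_NAMES:
        (out_dir / name).mkdir(exist_ok=True)
    for img, gt in zip(images, truths):
        rel = f"{gt.label.name}/{img.source_id.rsplit('/', 1)[-1]}.png"
        arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(out_dir / rel)
        manifest.append(
            {
                "path": rel,
                "label": gt.label.name,
                "tumors": [
                    {
                        "center": list(t.center),
                        "equivalent_radius": t.radius,
                        "kind": t.kind,
                        "circularity": t.circularity,
                    }
                    for t in gt.tumors
                ],
            }
        )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def rule_based_label(img: LabeledImage, params: PhantomParams | None = None) -> ClassLabel:
    """Shape-rule oracle: threshold, count components, score circularity.

    Inverts the palette through its monotone luminance, thresholds at the
    detection level, labels connected components inside the frame, and
    calls each component benign or malignant by comparing its circularity
    with the midpoint of the configured benign/malignant band.  Recovers
    the true class of generated images essentially always at default
    parameters; narrowing the circularity band degrades it (the
    separability knob).
    """
    params = params or PhantomParams()
    lum = img.pixels @ np.array([0.2126, 0.7152, 0.0722])
    thresh = params.palette.luminance(params.detection_threshold)
    mask = lum > thresh
    cc = _cc_label(mask)
    comps = [r for r in regionprops(cc) if r.area >= 6]
    if len(comps) == 0:
        return ClassLabel.NT
    midpoint = 0.5 * (params.benign_circularity_min + params.malignant_circularity_max)
    kinds = []
    for r in comps:
        circ = 4.0 * np.pi * r.area / r.perimeter**2 if r.perimeter > 0 else 0.0
        kinds.append("benign" if circ >= midpoint else "malignant")
    if len(kinds) == 1:
        return ClassLabel.BT if kinds[0] == "benign" else ClassLabel.MT
    # two or more: classify on the two largest components
    order = np.argsort([-r.area for r in comps])[:2]
    pair = sorted(kinds[i] for i in order)
    if pair == ["benign", "benign"]:
        return ClassLabel.BBT
    if pair == ["malignant", "malignant"]:
        return ClassLabel.MMT
    return ClassLabel.BMT
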
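"""Synthetic data generators with known ground truth.

Two families of generators make every pipeline stage testable offline:

* a specimen cohort generator in which a single latent morphology axis ``m``
  (fat near 0, invasive cancer near 0.5, fibroglandular near 1) drives both
  the tissue volume fractions (logistic adipose, peaked epithelium, stroma as
  the remainder) and the three optical scattering properties (monotone affine
  maps of ``m`` plus Gaussian noise), with class sizes 10/16/5 by default;
* an H&E-like slide renderer that lays out regions of known tissue type as
  stain optical densities and converts them to RGB.

``generate_exact_cohort`` is a variant whose fraction curves lie exactly in
the fitted model families (logistic / Gaussian composed with affine property
maps stays in-family), used for closed-loop recovery tests at zero noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .histology import default_stain_vectors
from .models import OpticalPropertyMap, logistic2, gaussian3, PROPERTY_NAMES, FRACTION_NAMES
from .pipeline import COHORT_COLUMNS

__all__ = [
    "SyntheticCohortConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_exact_cohort",
    "generate_hne_image",
    "make_fixture_suite",
]

CLASS_ORDER = ("invasive", "fibroglandular", "fat")

#: Latent-axis intervals per class: Beta(2, 2) draws are scaled into these so
#: that every specimen sits strictly inside its decision region at zero noise.
CLASS_M_INTERVALS = {
    "fat": (0.02, 0.24),
    "invasive": (0.43, 0.57),
    "fibroglandular": (0.72, 0.98),
}

#: Tighter intervals for the exact-family generator (its stroma curve differs).
EXACT_CLASS_M_INTERVALS = {
    "fat": (0.03, 0.20),
    "invasive": (0.38, 0.57),
    "fibroglandular": (0.65, 0.95),
}

#: Monotone affine property maps of the latent axis: value = intercept + slope * m.
PROPERTY_AFFINE = {
    "mus_prime": (0.5, 1.5),
    "gamma": (1.9, -0.5),
    "b_power": (0.2, 1.3),
}


@dataclass
class SyntheticCohortConfig:
    """Knobs of the cohort generator; defaults emulate a 31-specimen surgical
    cohort (10 invasive / 16 fibroglandular / 5 fat)."""

    n_invasive: int = 10
    n_fibroglandular: int = 16
    n_fat: int = 5
    pixels_per_specimen: tuple[int, int] = (200, 3000)
    noise_sd: float = 0.05  # per-property Gaussian noise, pre-smoothing
    fraction_noise_sd: float = 0.05  # noise on observed specimen fractions
    pixel_jitter_sd: float = 0.03  # latent-axis pixel jitter (post-smoothing sd)
    blur_mm: float = 1.0  # spatial smoothing scale of pixel noise
    pixel_size_mm: float = 0.5
    adipose_center: float = 0.35
    adipose_width: float = 0.05
    epithelium_peak_m: float = 0.5
    epithelium_width: float = 0.13
    epithelium_amplitude: float = 0.9
    renormalize_fractions: bool = False  # divide noisy fractions by their sum
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_invasive", "n_fibroglandular", "n_fat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("noise_sd", "fraction_noise_sd", "pixel_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            "invasive": self.n_invasive,
            "fibroglandular": self.n_fibroglandular,
            "fat": self.n_fat,
        }


@dataclass
class GroundTruth:
    """True latent state, fractions and class per specimen (and per pixel)."""

    specimens: pd.DataFrame
    pixel_maps: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)


def _true_fractions(m: np.ndarray, config: SyntheticCohortConfig):
    """Generator curves: logistic adipose, peaked epithelium, stroma = rest."""
    m = np.asarray(m, float)
    adipose = logistic2(m, config.adipose_center, config.adipose_width)
    peak = config.epithelium_amplitude * np.exp(
        -((m - config.epithelium_peak_m) ** 2) / (2.0 * config.epithelium_width**2)
    )
    epithelium = (1.0 - adipose) * peak
    stroma = 1.0 - adipose - epithelium
    if np.any(stroma < -1e-12):
        raise ValueError("inconsistent generator curves: negative stroma")
    return epithelium, np.clip(stroma, 0.0, None), np.asarray(adipose, float)


def _property_value(name: str, m) -> np.ndarray:
    intercept, slope = PROPERTY_AFFINE[name]
    return intercept + slope * np.asarray(m, float)


def _draw_class_latents(rng: np.random.Generator, counts, intervals) -> list[tuple[str, float]]:
    out = []
    for cls in CLASS_ORDER:
        lo, hi = intervals[cls]
        draws = rng.beta(2.0, 2.0, size=counts[cls])
        for m in lo + (hi - lo) * draws:
            out.append((cls, float(m)))
    return out


def _grid_shape(n_pixels: int) -> tuple[int, int]:
    side = max(2, int(round(np.sqrt(n_pixels))))
    return side, side


def _smooth_noise(
    rng: np.random.Generator, shape: tuple[int, int], sigma: float, sd: float
) -> np.ndarray:
    """Spatially smoothed Gaussian noise rescaled to standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    noise = rng.normal(0.0, 1.0, size=shape)
    if sigma > 0:
        noise = gaussian_filter(noise, sigma=sigma)
        scale = noise.std()
        if scale > 0:
            noise = noise / scale
    return noise * sd


def generate_cohort(
    config: SyntheticCohortConfig | None = None,
) -> tuple[pd.DataFrame, GroundTruth, dict[str, OpticalPropertyMap]]:
    """Generate a specimen cohort with per-pixel optical property maps.

    Per specimen: draw the latent axis ``m`` from its class distribution,
    jitter it per pixel with spatially smoothed Gaussian noise, evaluate the
    generator curves for true fractions, and map ``m`` through fixed monotone
    affine functions plus smoothed Gaussian noise for the three properties.
    Observed specimen fractions are the pixel-mean true fractions plus
    additive noise, clipped and renormalized to the simplex. Same seed, same
    output.
    """
    config = config or SyntheticCohortConfig()
    rng = np.random.default_rng(config.seed)
    latents = _draw_class_latents(rng, config.class_counts, CLASS_M_INTERVALS)
    sigma_px = config.blur_mm / config.pixel_size_mm

    rows = []
    spec_truth = []
    pixel_maps: dict[str, dict[str, np.ndarray]] = {}
    property_maps: dict[str, OpticalPropertyMap] = {}
    for i, (cls, m_spec) in enumerate(latents):
        sid = f"S{i + 1:03d}"
        n_pix = int(rng.integers(config.pixels_per_specimen[0], config.pixels_per_specimen[1] + 1))
        shape = _grid_shape(n_pix)

        jitter = _smooth_noise(rng, shape, sigma_px, config.pixel_jitter_sd)
        m_pix = np.clip(m_spec + jitter, 0.0, 1.0)
        epi_pix, str_pix, adi_pix = _true_fractions(m_pix, config)

        props = {}
        for prop in PROPERTY_NAMES:
            noise = _smooth_noise(rng, shape, sigma_px, config.noise_sd)
            props[prop] = _property_value(prop, m_pix) + noise
        props["mus_prime"] = np.clip(props["mus_prime"], 1e-3, None)
        property_maps[sid] = OpticalPropertyMap(
            mus_prime=props["mus_prime"],
            gamma=props["gamma"],
            b_power=props["b_power"],
            pixel_size=config.pixel_size_mm,
            specimen_id=sid,
        )

        true_fracs = np.array([epi_pix.mean(), str_pix.mean(), adi_pix.mean()])
        observed = true_fracs + rng.normal(0.0, config.fraction_noise_sd, size=3)
        observed = np.clip(observed, 0.0, 1.0)
        if config.renormalize_fractions:
            total = observed.sum()
            observed = observed / total if total > 0 else np.array([0.0, 0.0, 1.0])

        row = {"specimen_id": sid, "class": cls, "subtype": ""}
        for prop in PROPERTY_NAMES:
            row[f"{prop}_mean"] = float(props[prop].mean())
            row[f"{prop}_std"] = float(np.std(props[prop], ddof=1))
        for name, obs, (t, spread) in zip(
            FRACTION_NAMES,
            observed,
            [(epi_pix.mean(), epi_pix.std(ddof=1)),
             (str_pix.mean(), str_pix.std(ddof=1)),
             (adi_pix.mean(), adi_pix.std(ddof=1))],
        ):
            row[f"{name}_mean"] = float(obs)
            row[f"{name}_std"] = float(spread)
        rows.append(row)

        spec_truth.append(
            {
                "specimen_id": sid,
                "class": cls,
                "m": m_spec,
                "epithelium_true": float(true_fracs[0]),
                "stroma_true": float(true_fracs[1]),
                "adipose_true": float(true_fracs[2]),
            }
        )
        pixel_maps[sid] = {
            "m": m_pix,
            "epithelium": epi_pix,
            "stroma": str_pix,
            "adipose": adi_pix,
            "class": cls,
        }

    cohort = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    truth = GroundTruth(specimens=pd.DataFrame(spec_truth), pixel_maps=pixel_maps)
    return cohort, truth, property_maps


def generate_exact_cohort(
    config: SyntheticCohortConfig | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Noise-free cohort whose curves lie exactly in the fitted families.

    Fractions are logistic2 / gaussian3 functions of the latent axis and the
    properties are noise-free affine maps of it, so every fraction-versus-
    property relationship is exactly representable by the fitted model family
    (the three fractions do not sum exactly to 1 in this mode).
    """
    config = config or SyntheticCohortConfig()
    rng = np.random.default_rng(config.seed)
    latents = _draw_class_latents(rng, config.class_counts, EXACT_CLASS_M_INTERVALS)

    rows = []
    spec_truth = []
    for i, (cls, m) in enumerate(latents):
        sid = f"S{i + 1:03d}"
        adipose = logistic2(m, 0.25, 0.06)
        stroma = logistic2(m, 0.55, -0.08)
        epithelium = gaussian3(m, 0.85, 0.5, 0.10)
        row = {"specimen_id": sid, "class": cls, "subtype": ""}
        for prop in PROPERTY_NAMES:
            row[f"{prop}_mean"] = float(_property_value(prop, m))
            row[f"{prop}_std"] = 0.0
        for name, value in zip(FRACTION_NAMES, (epithelium, stroma, adipose)):
            row[f"{name}_mean"] = float(value)
            row[f"{name}_std"] = 0.0
        rows.append(row)
        spec_truth.append(
            {
                "specimen_id": sid,
                "class": cls,
                "m": m,
                "epithelium_true": float(epithelium),
                "stroma_true": float(stroma),
                "adipose_true": float(adipose),
            }
        )
    cohort = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return cohort, GroundTruth(specimens=pd.DataFrame(spec_truth))


#: Mean stain optical densities per rendered tissue type.
TISSUE_OD = {
    "epithelial": {"hematoxylin": 0.60, "eosin": 0.05},
    "stromal": {"hematoxylin": 0.05, "eosin": 0.50},
    "adipose": {"hematoxylin": 0.005, "eosin": 0.005},
}


def _paint_region(mask: np.ndarray, shape_spec: dict) -> None:
    kind = shape_spec.get("type", "rect")
    h, w = mask.shape
    if kind == "rect":
        r0, c0 = int(shape_spec["row0"]), int(shape_spec["col0"])
        r1, c1 = int(shape_spec["row1"]), int(shape_spec["col1"])
        mask[max(r0, 0) : min(r1, h), max(c0, 0) : min(c1, w)] = True
    elif kind == "circle":
        rr, cc = np.ogrid[:h, :w]
        dist2 = (rr - float(shape_spec["row"])) ** 2 + (cc - float(shape_spec["col"])) ** 2
        mask[dist2 <= float(shape_spec["radius"]) ** 2] = True
    else:
        raise ValueError(f"unknown shape type {kind!r}")


def generate_hne_image(
    region_layout,
    resolution: float = 500.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    canvas_shape: tuple[int, int] = (256, 256),
    background: str = "adipose",
):
    """Render an H&E-like RGB slide with a known per-pixel tissue label map.

    ``region_layout`` is a list of ``(shape_spec, tissue_type)`` pairs drawn
    in order (last drawn wins on overlap) onto a ``background`` canvas.
    Epithelial regions get high hematoxylin OD, stromal regions high eosin
    OD, adipose near-white; pixel RGB = 255 * 10^(-sum OD * V).

    Returns ``(pixels, resolution, label_map)`` where ``label_map`` holds the
    true tissue type name per pixel.
    """
    rng = np.random.default_rng(seed)
    labels = np.full(canvas_shape, background, dtype=object)
    for shape_spec, tissue in region_layout:
        if tissue not in TISSUE_OD:
            raise ValueError(f"unknown tissue type {tissue!r}")
        mask = np.zeros(canvas_shape, dtype=bool)
        _paint_region(mask, shape_spec)
        labels[mask] = tissue

    od_h = np.zeros(canvas_shape)
    od_e = np.zeros(canvas_shape)
    for tissue, ods in TISSUE_OD.items():
        sel = labels == tissue
        od_h[sel] = ods["hematoxylin"]
        od_e[sel] = ods["eosin"]
    if noise_sd > 0:
        od_h = np.clip(od_h + rng.normal(0.0, noise_sd, canvas_shape), 0.0, None)
        od_e = np.clip(od_e + rng.normal(0.0, noise_sd, canvas_shape), 0.0, None)

    vectors = default_stain_vectors()
    total_od = od_h[..., None] * vectors[0] + od_e[..., None] * vectors[1]
    pixels = np.clip(np.rint(255.0 * 10.0 ** (-total_od)), 0, 255).astype(np.uint8)
    return pixels, float(resolution), labels.astype(str)


LABEL_CODES = {"adipose": 0, "epithelial": 1, "stromal": 2}


def make_fixture_suite(out_dir, seed: int = 7) -> dict[str, Path]:
    """Write a small deterministic fixture tree for tests and docs.

    Contents: one slide per dominant tissue, one heterogeneous slide
    (a malignant lesion surrounded by fat), their true label maps, and a
    default synthetic cohort with per-specimen optical property maps.
    """
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    slides_dir = out_dir / "slides"
    labels_dir = out_dir / "labels"
    maps_dir = out_dir / "maps"
    for d in (slides_dir, labels_dir, maps_dir):
        d.mkdir(exist_ok=True)
    written: dict[str, Path] = {}

    pure = {
        "epithelial": [({"type": "rect", "row0": 0, "col0": 0, "row1": 256, "col1": 256}, "epithelial")],
        "stromal": [({"type": "rect", "row0": 0, "col0": 0, "row1": 256, "col1": 256}, "stromal")],
        "adipose": [],
    }
    hetero = [
        ({"type": "circle", "row": 128, "col": 128, "radius": 90}, "stromal"),
        ({"type": "circle", "row": 128, "col": 128, "radius": 55}, "epithelial"),
    ]
    layouts = dict(pure)
    layouts["heterogeneous"] = hetero

    for name, layout in layouts.items():
        pixels, _, label_map = generate_hne_image(
            layout, resolution=500.0, noise_sd=0.02, seed=seed
        )
        slide_path = slides_dir / f"{name}.png"
        Image.fromarray(pixels).save(slide_path)
        coded = np.vectorize(LABEL_CODES.get)(label_map).astype(np.uint8)
        label_path = labels_dir / f"{name}_labels.png"
        Image.fromarray(coded, mode="L").save(label_path)
        written[f"slide_{name}"] = slide_path
        written[f"labels_{name}"] = label_path

    config = SyntheticCohortConfig(seed=seed)
    cohort, truth, property_maps = generate_cohort(config)
    cohort_path = out_dir / "cohort.csv"
    cohort.to_csv(cohort_path, index=False, float_format="%.9g")
    truth_path = out_dir / "ground_truth.csv"
    truth.specimens.to_csv(truth_path, index=False, float_format="%.9g")
    for sid, pmap in property_maps.items():
        stack = np.stack([pmap.mus_prime, pmap.gamma, pmap.b_power]).astype(np.float32)
        tifffile.imwrite(maps_dir / f"{sid}_props.tif", stack, photometric="minisblack")
    config_path = out_dir / "config.json"
    with open(config_path, "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
    written["cohort"] = cohort_path
    written["ground_truth"] = truth_path
    written["config"] = config_path
    written["maps_dir"] = maps_dir
    return written
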
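"""Histology prediction from optical properties and threshold classification.

Nine fitted curves (three tissue fractions x three scattering properties) are
combined into per-specimen or per-pixel fraction predictions: each fraction is
the mean of its three property predictions, each clipped to [0, 1] first and
never renormalized. Specimens are validated by leave-one-out cross-validation,
then classified as fat (adipose > 0.5), malignant (epithelium:stroma ratio
> 1) or benign, and rendered as soft classification maps whose color
saturation encodes distance from the decision thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    FAMILY_FOR_FRACTION,
    FRACTION_NAMES,
    PROPERTY_NAMES,
    FitError,
    ModelFamily,
    OpticalPropertyMap,
    ScatterModel,
    fit_model,
)

__all__ = [
    "CLASS_LABELS",
    "TRUE_CLASS_TO_OUTPUT",
    "PredictionResult",
    "SoftClassMap",
    "ModelSet",
    "fit_all_models",
    "predict_fractions",
    "predict_fraction_maps",
    "ep_st_ratio",
    "classify",
    "classify_arrays",
    "loo_cv",
    "soft_classification_map",
    "overlay_on_photograph",
]

#: Classifier output classes, in fixed order.
CLASS_LABELS = ("malignant", "benign", "fat")

#: Pathology cohort label -> classifier output class.
TRUE_CLASS_TO_OUTPUT = {
    "invasive": "malignant",
    "fibroglandular": "benign",
    "fat": "fat",
}

#: Display colors (RGB in [0,1]): purple malignant, pink benign, yellow fat.
CLASS_COLORS = {
    "malignant": (0.50, 0.10, 0.55),
    "benign": (0.95, 0.45, 0.60),
    "fat": (0.95, 0.85, 0.20),
}

#: Cohort CSV column schema (per-specimen table).
COHORT_COLUMNS = (
    ["specimen_id", "class", "subtype"]
    + [f"{p}_{s}" for p in PROPERTY_NAMES for s in ("mean", "std")]
    + [f"{f}_{s}" for f in FRACTION_NAMES for s in ("mean", "std")]
)


@dataclass
class PredictionResult:
    """Predicted tissue fractions for one specimen or pixel."""

    epithelium: float
    stroma: float
    adipose: float
    components: dict[str, dict[str, float]]
    ep_st_ratio: float
    predicted_class: str


@dataclass
class SoftClassMap:
    """Per-pixel class labels with a saturation weight in [0, 1]."""

    classes: np.ndarray  # array of strings from CLASS_LABELS
    saturation: np.ndarray

    def __post_init__(self) -> None:
        if self.classes.shape != self.saturation.shape:
            raise ValueError("class and saturation grids must match")
        if np.any(self.saturation < 0) or np.any(self.saturation > 1):
            raise ValueError("saturation must lie in [0, 1]")

    def to_rgb(self) -> np.ndarray:
        """Render as an RGB image: class color blended toward white at the
        decision threshold (saturation 0)."""
        rgb = np.ones(self.classes.shape + (3,), dtype=float)
        for name, color in CLASS_COLORS.items():
            sel = self.classes == name
            blend = self.saturation[sel][:, None]
            rgb[sel] = (1.0 - blend) + blend * np.asarray(color)
        return rgb


class ModelSet(dict):
    """Mapping (fraction_name, property_name) -> fitted ScatterModel."""

    def require_complete(self) -> None:
        for f in FRACTION_NAMES:
            for p in PROPERTY_NAMES:
                if (f, p) not in self:
                    raise KeyError(f"missing model for ({f}, {p})")

    @classmethod
    def from_models(cls, models: Iterable[ScatterModel]) -> "ModelSet":
        out = cls()
        for m in models:
            out[(m.fraction_name, m.property_name)] = m
        return out

    def models(self) -> list[ScatterModel]:
        return [self[(f, p)] for f in FRACTION_NAMES for p in PROPERTY_NAMES]


def fit_all_models(cohort: pd.DataFrame, seed: int = 0) -> ModelSet:
    """Fit all nine fraction-versus-property curves on specimen ROI means."""
    out = ModelSet()
    for fraction in FRACTION_NAMES:
        family = FAMILY_FOR_FRACTION[fraction]
        for prop in PROPERTY_NAMES:
            out[(fraction, prop)] = fit_model(
                cohort[f"{prop}_mean"].to_numpy(),
                cohort[f"{fraction}_mean"].to_numpy(),
                family,
                property_name=prop,
                fraction_name=fraction,
                seed=seed,
            )
    return out


def ep_st_ratio(epithelium, stroma):
    """Epithelium / stroma ratio; +inf when stroma is 0 with epithelium > 0,
    and 0 when both are 0 (no epithelium -> benign side)."""
    epithelium = np.asarray(epithelium, float)
    stroma = np.asarray(stroma, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            stroma > 0,
            epithelium / np.where(stroma > 0, stroma, 1.0),
            np.where(epithelium > 0, np.inf, 0.0),
        )
    return ratio if ratio.ndim else float(ratio)


def classify_arrays(
    epithelium,
    stroma,
    adipose,
    fat_threshold: float = 0.5,
    ratio_threshold: float = 1.0,
):
    """Vectorized three-way classification (strict thresholds).

    adipose > fat_threshold -> fat; else epithelium:stroma ratio >
    ratio_threshold -> malignant; else benign.
    """
    adipose = np.asarray(adipose, float)
    ratio = np.asarray(ep_st_ratio(epithelium, stroma))
    out = np.where(
        adipose > fat_threshold,
        "fat",
        np.where(ratio > ratio_threshold, "malignant", "benign"),
    )
    return out if out.ndim else str(out)


def classify(
    prediction: "PredictionResult",
    fat_threshold: float = 0.5,
    ratio_threshold: float = 1.0,
) -> str:
    """Classify one prediction as malignant / benign / fat."""
    return classify_arrays(
        prediction.epithelium,
        prediction.stroma,
        prediction.adipose,
        fat_threshold,
        ratio_threshold,
    )


def predict_fractions(
    models: ModelSet,
    properties: Mapping[str, float],
    fat_threshold: float = 0.5,
    ratio_threshold: float = 1.0,
) -> PredictionResult:
    """Predict all three fractions from one (mus_prime, gamma, b_power) triple.

    Each fraction is the mean of its three per-property model predictions,
    each clipped to [0, 1] before averaging; the final fractions are not
    renormalized to sum to 1.
    """
    models.require_complete()
    components: dict[str, dict[str, float]] = {}
    finals: dict[str, float] = {}
    for fraction in FRACTION_NAMES:
        per_prop = {}
        for prop in PROPERTY_NAMES:
            value = float(models[(fraction, prop)].predict(float(properties[prop])))
            per_prop[prop] = float(np.clip(value, 0.0, 1.0))
        components[fraction] = per_prop
        finals[fraction] = float(np.mean(list(per_prop.values())))
    ratio = ep_st_ratio(finals["epithelium"], finals["stroma"])
    predicted = classify_arrays(
        finals["epithelium"], finals["stroma"], finals["adipose"],
        fat_threshold, ratio_threshold,
    )
    return PredictionResult(
        epithelium=finals["epithelium"],
        stroma=finals["stroma"],
        adipose=finals["adipose"],
        components=components,
        ep_st_ratio=float(ratio),
        predicted_class=str(predicted),
    )


def predict_fraction_maps(
    models: ModelSet, props: OpticalPropertyMap
) -> dict[str, np.ndarray]:
    """Per-pixel fraction predictions over an optical property map.

    Returns arrays keyed epithelium / stroma / adipose / ep_st_ratio; pixels
    outside the validity mask are NaN.
    """
    models.require_complete()
    out: dict[str, np.ndarray] = {}
    invalid = ~props.valid_mask
    for fraction in FRACTION_NAMES:
        stackup = []
        for prop in PROPERTY_NAMES:
            pred = np.clip(models[(fraction, prop)].predict(props.property_array(prop)), 0, 1)
            stackup.append(pred)
        merged = np.mean(stackup, axis=0)
        merged[invalid] = np.nan
        out[fraction] = merged
    ratio = np.asarray(ep_st_ratio(out["epithelium"], out["stroma"]), float)
    ratio[invalid] = np.nan
    out["ep_st_ratio"] = ratio
    return out


def loo_cv(
    cohort: pd.DataFrame,
    fat_threshold: float = 0.5,
    ratio_threshold: float = 1.0,
    seed: int = 0,
    collect_models: dict | None = None,
) -> pd.DataFrame:
    """Leave-one-out cross-validation of the nine-curve prediction model.

    For each specimen, all nine models are refitted on the remaining
    specimens and the held-out specimen's fractions are predicted from its
    property means. A fold whose training fit fails is recorded with a
    ``fold_error`` message rather than silently dropped. Output row order
    follows the input; the per-specimen result is independent of cohort
    ordering. When ``collect_models`` is a dict it receives each fold's
    fitted :class:`ModelSet` keyed by the held-out specimen id (useful for
    rendering that specimen's per-pixel maps without refitting).
    """
    if len(cohort) < 4:
        raise ValueError("LOO-CV needs at least 4 specimens")
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns and c != "subtype"]
    if missing:
        raise ValueError(f"cohort is missing columns: {missing}")

    rows = []
    for idx in cohort.index:
        train = cohort.drop(index=idx)
        test = cohort.loc[idx]
        record: dict = {
            "specimen_id": test["specimen_id"],
            "class": test["class"],
            "fold_error": "",
        }
        try:
            fold_models = fit_all_models(train, seed=seed)
            if collect_models is not None:
                collect_models[test["specimen_id"]] = fold_models
            properties = {p: float(test[f"{p}_mean"]) for p in PROPERTY_NAMES}
            result = predict_fractions(
                fold_models, properties, fat_threshold, ratio_threshold
            )
        except FitError as exc:
            record["fold_error"] = str(exc)
            for fraction in FRACTION_NAMES:
                record[f"{fraction}_pred"] = np.nan
                for prop in PROPERTY_NAMES:
                    record[f"{fraction}_pred_{prop}"] = np.nan
            record["ep_st_ratio"] = np.nan
            record["predicted_class"] = ""
        else:
            for fraction in FRACTION_NAMES:
                record[f"{fraction}_pred"] = getattr(result, fraction)
                for prop in PROPERTY_NAMES:
                    record[f"{fraction}_pred_{prop}"] = result.components[fraction][prop]
            record["ep_st_ratio"] = result.ep_st_ratio
            record["predicted_class"] = result.predicted_class
        for fraction in FRACTION_NAMES:
            if f"{fraction}_mean" in cohort.columns:
                record[f"{fraction}_true"] = float(test[f"{fraction}_mean"])
        rows.append(record)
    return pd.DataFrame(rows)


def soft_classification_map(
    fraction_maps: Mapping[str, np.ndarray],
    fat_threshold: float = 0.5,
    ratio_threshold: float = 1.0,
) -> SoftClassMap:
    """Build a soft classification map from per-pixel fraction predictions.

    Saturation is the clipped distance from the decision threshold:
    ``min(1, |ratio - ratio_threshold|)`` for glandular pixels (white at the
    threshold, full color at ratio 0 or 2) and
    ``min(1, |adipose - fat_threshold| / fat_threshold)`` for fat pixels.
    """
    epithelium = np.asarray(fraction_maps["epithelium"], float)
    stroma = np.asarray(fraction_maps["stroma"], float)
    adipose = np.asarray(fraction_maps["adipose"], float)
    classes = np.asarray(classify_arrays(
        epithelium, stroma, adipose, fat_threshold, ratio_threshold
    ))
    ratio = np.asarray(ep_st_ratio(epithelium, stroma), float)
    with np.errstate(invalid="ignore"):
        glandular_sat = np.minimum(1.0, np.abs(ratio - ratio_threshold))
        fat_sat = np.minimum(1.0, np.abs(adipose - fat_threshold) / fat_threshold)
    saturation = np.where(classes == "fat", fat_sat, glandular_sat)
    saturation = np.nan_to_num(saturation, nan=0.0)
    return SoftClassMap(classes=classes, saturation=saturation)


def overlay_on_photograph(
    soft_map: SoftClassMap, photo: np.ndarray
) -> np.ndarray:
    """Alpha-composite a soft classification map onto a photograph.

    Per-pixel alpha equals the soft-map saturation; fat pixels are fully
    transparent (adipose is distinguishable by inspection, so it is not
    overlaid). Returns an 8-bit RGB image.
    """
    photo = np.asarray(photo)
    if photo.ndim != 3 or photo.shape[-1] != 3:
        raise ValueError("photo must be an (H, W, 3) RGB image")
    if photo.shape[:2] != soft_map.classes.shape:
        raise ValueError("soft map and photograph grids do not match")
    alpha = np.where(soft_map.classes == "fat", 0.0, soft_map.saturation)[..., None]
    color = np.zeros(photo.shape, dtype=float)
    for name, rgb in CLASS_COLORS.items():
        color[soft_map.classes == name] = np.asarray(rgb) * 255.0
    blended = (1.0 - alpha) * photo.astype(float) + alpha * color
    return np.clip(np.rint(blended), 0, 255).astype(np.uint8)
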
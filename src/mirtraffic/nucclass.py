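"""Nuclei phenotype classification: interphase, mitosis, apoptosis, artefact.

Features are morphology + normalized-intensity summaries per segmented
nucleus; the classifier is a class-weighted RBF-kernel SVM evaluated by
stratified four-fold cross-validation.  Intensity features are computed
after per-image grey-value normalization (background median -> 0,
nuclei-pixel median -> 1) so they compare across experiments with
different illumination.

The fixed feature list (one row per nucleus):

    area, perimeter, eccentricity, solidity, extent,
    mean_intensity, sd_intensity, q10, q50, q90 (normalized grey values),
    integrated_intensity, n_fragments (connected components of the label),
    n_intensity_splits (components above the 60% intensity quantile),
    gradient_energy (mean Sobel magnitude inside the object).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

CLASSES = ("interphase", "mitosis", "apoptosis", "artefact")
MIN_PIXELS = 5

FEATURE_COLUMNS = [
    "area",
    "perimeter",
    "eccentricity",
    "solidity",
    "extent",
    "mean_intensity",
    "sd_intensity",
    "q10",
    "q50",
    "q90",
    "integrated_intensity",
    "n_fragments",
    "n_intensity_splits",
    "gradient_energy",
]


@dataclass
class ConfusionMatrix:
    counts: pd.DataFrame  # rows = true class, columns = predicted
    overall_accuracy: float
    per_class_accuracy: dict
    overfit_warning: bool = False


def normalize_grey(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Scale so the background median is 0 and the nuclei-pixel median is 1."""
    image = np.asarray(image, dtype=np.float64)
    bg = np.median(image[mask == 0]) if (mask == 0).any() else 0.0
    fg = np.median(image[mask > 0]) if (mask > 0).any() else bg + 1.0
    scale = fg - bg
    if scale <= 0:
        scale = 1.0
    return (image - bg) / scale


def extract_features(field, mask: np.ndarray) -> pd.DataFrame:
    """One feature vector per label; labels under 5 px are excluded and logged.

    ``field`` is an :class:`~mirtraffic.imagequant.ImageField` with a
    ``nuclei`` channel (or a bare 2-D array).
    """
    image = field.channels["nuclei"] if hasattr(field, "channels") else field
    norm = normalize_grey(image, mask)
    grad = filters.sobel(norm)
    rows = []
    for lab in np.unique(mask[mask > 0]):
        obj = mask == lab
        npix = int(obj.sum())
        if npix < MIN_PIXELS:
            logger.info("label %d has %d px (<%d), excluded", lab, npix, MIN_PIXELS)
            continue
        vals = norm[obj]
        # shape features on the filled union of the label's fragments
        props = measure.regionprops(obj.astype(np.uint8))[0]
        _, n_frag = ndimage.label(obj)
        split_mask = obj & (norm > np.quantile(vals, 0.6))
        _, n_split = ndimage.label(split_mask)
        rows.append(
            {
                "label": int(lab),
                "area": float(npix),
                "perimeter": float(props.perimeter),
                "eccentricity": float(props.eccentricity),
                "solidity": float(props.solidity),
                "extent": float(props.extent),
                "mean_intensity": float(vals.mean()),
                "sd_intensity": float(vals.std()),
                "q10": float(np.quantile(vals, 0.1)),
                "q50": float(np.quantile(vals, 0.5)),
                "q90": float(np.quantile(vals, 0.9)),
                "integrated_intensity": float(vals.sum()),
                "n_fragments": float(n_frag),
                "n_intensity_splits": float(max(n_split, 1)),
                "gradient_energy": float(grad[obj].mean()),
            }
        )
    return pd.DataFrame(rows, columns=["label"] + FEATURE_COLUMNS)


def _make_svm(class_weights, seed: int) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel="rbf",
                    C=1.0,
                    gamma="scale",
                    class_weight=class_weights,
                    random_state=seed,
                ),
            ),
        ]
    )


def train_classifier(
    features: pd.DataFrame,
    labels,
    class_weights="balanced",
    folds: int = 4,
    seed: int = 0,
) -> tuple[Pipeline, ConfusionMatrix]:
    """Weighted SVM with stratified k-fold cross-validated confusion matrix.

    ``class_weights='balanced'`` applies inverse-class-frequency
    misclassification weights.  The returned model is refit on all data;
    the confusion matrix comes from out-of-fold predictions and is
    deterministic given the seed.
    """
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = np.asarray(labels)
    present = pd.unique(y)
    missing = [c for c in CLASSES if c not in present] if set(present) <= set(CLASSES) else []
    if missing:
        raise ValueError(f"classes absent from training data: {missing}")
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        raise ValueError(f"need >= {folds} examples per class, got {counts.to_dict()}")
    model = _make_svm(class_weights, seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(model, X, y, cv=cv)
    order = [c for c in CLASSES if c in present] or sorted(present)
    cm = _sk_confusion(y, pred, labels=order)
    cm_df = pd.DataFrame(cm, index=order, columns=order)
    overall = float(np.trace(cm) / cm.sum())
    per_class = {
        c: float(cm_df.loc[c, c] / cm_df.loc[c].sum()) if cm_df.loc[c].sum() else np.nan
        for c in order
    }
    model.fit(X, y)
    overfit = False
    n_unique = pd.DataFrame(X).drop_duplicates().shape[0]
    if n_unique < len(order) * 2 and (model.predict(X) == y).all():
        overfit = True
        warnings.warn(
            "perfect resubstitution on near-duplicate training data; "
            "the cross-validated matrix is not informative",
            UserWarning,
            stacklevel=2,
        )
    return model, ConfusionMatrix(cm_df, overall, per_class, overfit)


def classify(model: Pipeline, features: pd.DataFrame) -> list:
    """Predict a phenotype label per nucleus (empty in, empty out)."""
    if len(features) == 0:
        return []
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    return list(model.predict(X))


def proliferation_readout(
    labels: pd.DataFrame,
    negative_control: str,
) -> pd.DataFrame:
    """Mitotic fraction and control-normalized total cells per condition.

    ``labels`` columns: condition, timepoint, phenotype.  Mitotic fraction
    = #mitosis / #non-artefact cells; the total cell count is divided by
    the negative control's total at the same time point (control = 1).
    """
    rows = []
    for (cond, tp), grp in labels.groupby(["condition", "timepoint"], sort=True):
        total = len(grp)
        non_artefact = (grp["phenotype"] != "artefact").sum()
        mitotic = (grp["phenotype"] == "mitosis").sum()
        rows.append(
            {
                "condition": cond,
                "timepoint": tp,
                "total_cells": total,
                "mitotic_fraction": mitotic / non_artefact if non_artefact else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    nc = out[out.condition == negative_control].set_index("timepoint")["total_cells"]
    if nc.empty:
        raise ValueError(f"negative control {negative_control!r} absent")
    out["normalized_total"] = [
        row.total_cells / nc[row.timepoint] if row.timepoint in nc.index else np.nan
        for row in out.itertuples()
    ]
    return out
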
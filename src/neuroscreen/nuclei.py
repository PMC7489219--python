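"""Nuclear segmentation and live/dead classification.

Fixed-endpoint Hoechst images are segmented with a classical pipeline:
morphological-opening background subtraction, global Otsu threshold,
distance-transform watershed to split touching nuclei, then border and
small-object removal.  Each nucleus is summarized by area, mean and
integrated intensity (measured on the original image) and eccentricity, and
classified as live or dead.  Dying neurons show pyknotic nuclei - condensed
and brightly stained - so the default classifier is a transparent
two-threshold rule: dead iff area < area_threshold AND mean intensity >
intensity_threshold (strict inequalities; a record exactly at a threshold is
live).  A linear (logistic) two-feature rule is available as an alternative.

Coordinates are 0-based row/col pixel centers; areas are in pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import regionprops_table
from skimage.morphology import disk, opening
from skimage.feature import peak_local_max
from skimage.segmentation import watershed, clear_border

__all__ = [
    "SegmentationParams",
    "ClassifierModel",
    "segment_nuclei",
    "extract_features",
    "calibrate_classifier",
    "classify_nuclei",
    "counts_by_well",
    "match_centroids",
]

FEATURES = ("area", "mean_intensity", "integrated_intensity", "eccentricity")


@dataclass
class SegmentationParams:
    """Tunables of the segmentation stage.

    ``bg_disc_radius`` defaults to 5x the expected mean nucleus radius so
    the opening removes everything nucleus-sized and leaves only the smooth
    background.  Objects under ``min_area`` px or touching the image border
    are discarded.
    """

    bg_disc_radius: int = 30
    min_area: int = 20
    peak_min_distance: int = 5
    exclude_border_objects: bool = True


@dataclass
class ClassifierModel:
    """Serializable live/dead decision rule.

    ``method="thresholds"``: dead iff area < area_threshold and mean
    intensity > intensity_threshold.  ``method="linear"``: dead iff
    w . (area, mean_intensity) + b > 0.  Calibration is deterministic:
    the same labeled set (and seed, for the linear rule) reproduces the
    same parameters.
    """

    method: str = "thresholds"
    feature_names: tuple[str, ...] = ("area", "mean_intensity")
    area_threshold: float | None = None
    intensity_threshold: float | None = None
    weights: list[float] | None = None
    bias: float | None = None
    n_train: int = 0
    train_accuracy: float = float("nan")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["feature_names"] = list(self.feature_names)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        d["feature_names"] = tuple(d["feature_names"])
        return cls(**d)


def segment_nuclei(image, params: SegmentationParams | None = None):
    """Segment nuclei in a single-channel image.

    Returns ``(labels, records)``: an integer label mask and a DataFrame
    with one row per object (label, centroid_row, centroid_col; feature
    columns unfilled).  An all-constant image yields zero objects.
    """
    params = params or SegmentationParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    empty = (
        np.zeros(img.shape, dtype=np.int32),
        pd.DataFrame(columns=["label", "centroid_row", "centroid_col"]),
    )
    if np.ptp(img) == 0:
        return empty

    footprint = disk(params.bg_disc_radius, decomposition="sequence")
    background = opening(img, footprint)
    corrected = img - background
    if np.ptp(corrected) == 0:
        return empty
    # Otsu on log-transformed intensities: nuclear brightness is bimodal
    # (pyknotic nuclei are several-fold brighter than live ones) and a linear
    # Otsu can settle between the two object classes instead of between
    # background and foreground; the log compresses the bright mode.
    log_img = np.log1p(np.clip(corrected, 0.0, None))
    mask = log_img > threshold_otsu(log_img)
    # noise floor: on an empty field Otsu merely bisects the camera noise, so
    # additionally require pixels to clear a robust (median + 5 MAD) estimate
    # of the background fluctuation
    mad = np.median(np.abs(corrected - np.median(corrected)))
    floor = np.median(corrected) + 5.0 * 1.4826 * mad
    mask &= corrected > floor
    if not mask.any():
        return empty

    distance = ndi.distance_transform_edt(mask)
    blobs, _ = ndi.label(mask)
    peaks = peak_local_max(
        distance,
        min_distance=params.peak_min_distance,
        labels=blobs,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask)

    if params.exclude_border_objects:
        labels = clear_border(labels)
    # drop small objects and relabel densely
    ids, sizes = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[sizes >= params.min_area]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    labels = remap[labels]
    if labels.max() == 0:
        return empty

    props = regionprops_table(labels, properties=("label", "centroid"))
    records = pd.DataFrame(
        {
            "label": props["label"],
            "centroid_row": props["centroid-0"],
            "centroid_col": props["centroid-1"],
        }
    )
    return labels, records


def extract_features(labels, image) -> pd.DataFrame:
    """Per-object features measured on the original (uncorrected) image.

    Returns one row per label: centroid, area (px), mean intensity (ADU),
    integrated intensity (ADU px), eccentricity.
    """
    labels = np.asarray(labels)
    img = np.asarray(image, dtype=float)
    if labels.shape != img.shape:
        raise ValueError("label mask and image shapes differ")
    if labels.max() == 0:
        return pd.DataFrame(
            columns=["label", "centroid_row", "centroid_col", *FEATURES]
        )
    props = regionprops_table(
        labels,
        intensity_image=img,
        properties=("label", "centroid", "area", "intensity_mean", "eccentricity"),
    )
    df = pd.DataFrame(
        {
            "label": props["label"],
            "centroid_row": props["centroid-0"],
            "centroid_col": props["centroid-1"],
            "area": props["area"].astype(float),
            "mean_intensity": props["intensity_mean"],
            "eccentricity": props["eccentricity"],
        }
    )
    df["integrated_intensity"] = df["area"] * df["mean_intensity"]
    return df[["label", "centroid_row", "centroid_col", *FEATURES]]


def _best_intensity_threshold(intens, is_dead, base_errors):
    """Given the subset predicted small-enough, find the intensity cut.

    Candidates sit between consecutive sorted intensity values (strict >
    rule).  Returns (errors, dead_recall_hits, threshold) minimizing errors;
    among ties prefers the lower threshold (more dead calls -> higher dead
    recall).
    """
    order = np.argsort(intens, kind="stable")
    iv = intens[order]
    dead = is_dead[order]
    n = iv.size
    # thresholds: below all values, between values, above all values
    cand = np.concatenate(([iv[0] - 1.0], (iv[:-1] + iv[1:]) / 2.0, [iv[-1] + 1.0]))
    # for candidate index j, records with intensity > cand[j] are called dead
    dead_cum = np.concatenate(([0], np.cumsum(dead)))  # dead with iv <= position
    live_cum = np.concatenate(([0], np.cumsum(~dead)))
    # records at positions >= j have iv > cand[j] is not exact with ties: use
    # searchsorted on the candidate values instead
    pos = np.searchsorted(iv, cand, side="right")
    dead_missed = dead_cum[pos]           # dead at/below the cut -> called live
    live_wrong = live_cum[n] - live_cum[pos]  # live above the cut -> called dead
    errors = base_errors + dead_missed + live_wrong
    j = int(np.argmin(errors))  # argmin takes the first (lowest threshold) tie
    dead_hits = dead_cum[n] - dead_cum[pos[j]]
    return int(errors[j]), int(dead_hits), float(cand[j])


def calibrate_classifier(
    records: pd.DataFrame,
    method: str = "thresholds",
    seed=None,
    label_column: str = "cls",
) -> ClassifierModel:
    """Fit the live/dead rule on labeled feature records.

    Requires >= 20 labeled examples per class.  The default method searches
    all (area, intensity) threshold pairs exhaustively and picks the pair
    minimizing training error, breaking ties toward higher dead recall.
    ``method="linear"`` fits an L2-regularized logistic regression on the
    same two features (deterministic given the data).
    """
    if label_column not in records.columns:
        raise ValueError(f"records need a {label_column!r} column")
    y = (records[label_column].to_numpy() == "dead")
    n_dead, n_live = int(y.sum()), int((~y).sum())
    if n_dead == 0 or n_live == 0:
        raise ValueError("calibration requires both classes in the labeled set")
    if min(n_dead, n_live) < 20:
        raise ValueError(
            f"need >= 20 labeled examples per class (got live={n_live}, "
            f"dead={n_dead})"
        )
    areas = records["area"].to_numpy(dtype=float)
    intens = records["mean_intensity"].to_numpy(dtype=float)
    n = y.size

    if method == "thresholds":
        uniq = np.unique(areas)
        area_cand = np.concatenate(
            ([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0])
        )
        best = None  # (errors, -dead_hits, -a_thr, i_thr, a_thr)
        for a_thr in area_cand:
            small = areas < a_thr
            base = int(y[~small].sum())  # dead above the area cut: missed
            if small.any():
                errs, hits, i_thr = _best_intensity_threshold(
                    intens[small], y[small], base
                )
            else:
                errs, hits, i_thr = base, 0, float(np.max(intens) + 1.0)
            key = (errs, -hits, -a_thr, i_thr)
            if best is None or key < best[0]:
                best = (key, float(a_thr), float(i_thr))
        (errs, neg_hits, _, _), a_thr, i_thr = best
        return ClassifierModel(
            method="thresholds",
            area_threshold=a_thr,
            intensity_threshold=i_thr,
            n_train=n,
            train_accuracy=1.0 - errs / n,
        )

    if method == "linear":
        from sklearn.linear_model import LogisticRegression

        X = np.column_stack([areas, intens])
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        clf = LogisticRegression(random_state=0).fit((X - mu) / sd, y)
        w = clf.coef_[0] / sd
        b = float(clf.intercept_[0] - np.dot(clf.coef_[0], mu / sd))
        acc = float(np.mean((X @ w + b > 0) == y))
        return ClassifierModel(
            method="linear",
            weights=[float(v) for v in w],
            bias=b,
            n_train=n,
            train_accuracy=acc,
        )

    raise ValueError(f"unknown method {method!r}")


def classify_nuclei(records: pd.DataFrame, model: ClassifierModel) -> pd.DataFrame:
    """Assign every record a predicted class ('live' or 'dead')."""
    for feat in model.feature_names:
        if feat not in records.columns:
            raise ValueError(f"missing feature column {feat!r}")
        if records[feat].isna().any():
            raise ValueError(f"feature {feat!r} contains missing values")
    out = records.copy()
    area = out["area"].to_numpy(dtype=float)
    intens = out["mean_intensity"].to_numpy(dtype=float)
    if model.method == "thresholds":
        dead = (area < model.area_threshold) & (intens > model.intensity_threshold)
    elif model.method == "linear":
        X = np.column_stack([area, intens])
        dead = X @ np.asarray(model.weights) + model.bias > 0
    else:
        raise ValueError(f"unknown method {model.method!r}")
    out["predicted_class"] = np.where(dead, "dead", "live")
    return out


def counts_by_well(records: pd.DataFrame, well_column: str = "well") -> pd.DataFrame:
    """Tally predicted live/dead per well into a counts table."""
    if "predicted_class" not in records.columns:
        raise ValueError("records must be classified first")
    g = records.groupby(well_column)["predicted_class"]
    out = pd.DataFrame(
        {
            "n_live": g.apply(lambda s: int((s == "live").sum())),
            "n_dead": g.apply(lambda s: int((s == "dead").sum())),
        }
    ).reset_index().rename(columns={well_column: "well"})
    out["n_total"] = out["n_live"] + out["n_dead"]
    return out


def match_centroids(
    detected: np.ndarray, truth: np.ndarray, max_dist: float = 5.0
) -> dict:
    """One-to-one nearest matching of detected to true centroids.

    Greedy by increasing distance with a ``max_dist`` gate; returns recall
    (matched / truth), precision (matched / detected) and the match count.
    """
    detected = np.atleast_2d(np.asarray(detected, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if truth.size == 0 or detected.size == 0:
        return {"n_matched": 0, "recall": 0.0 if truth.size else 1.0,
                "precision": 0.0 if detected.size else 1.0}
    tree = cKDTree(detected)
    dists, idx = tree.query(truth, k=1)
    order = np.argsort(dists)
    used_det, used_tru = set(), set()
    pairs = []
    for ti in order:
        if dists[ti] > max_dist:
            break
        di = idx[ti]
        if di in used_det:
            # nearest already taken; look for the next free detection
            extra_d, extra_i = tree.query(truth[ti], k=min(5, len(detected)))
            found = False
            for d, i in zip(np.atleast_1d(extra_d), np.atleast_1d(extra_i)):
                if d <= max_dist and i not in used_det:
                    di, found = int(i), True
                    dists[ti] = d
                    break
            if not found:
                continue
        used_det.add(int(di))
        used_tru.add(int(ti))
        pairs.append((int(ti), int(di), float(dists[ti])))
    n = len(pairs)
    return {
        "n_matched": n,
        "recall": n / len(truth),
        "precision": n / len(detected),
        "pairs": pairs,
    }
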
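"""End-to-end pipeline orchestration and run configuration.

Ties the stages together: segment -> classify -> counts -> survival ->
protection -> QC -> hits -> Z maps for the endpoint screen, and register ->
background -> ROI -> trace -> loss -> estimation stats for the TMRE assay.
A run's configuration (every threshold and the global seed) is serializable
and written next to its outputs together with its hash, so results are
reproducible and attributable.  The global seed is expanded into per-stage
substreams, so stages can be re-run in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estim_stats, nuclei, plate_stats, tmre
from .nuclei import ClassifierModel, SegmentationParams
from .plate_stats import PlateLayout, VEHICLE

__all__ = ["RunConfig", "ScreenResult", "TMREResult", "run_screen", "run_tmre",
           "label_records_from_truth"]


@dataclass
class RunConfig:
    """All tunables of a pipeline run, serializable as YAML/JSON."""

    seed: int = 0
    out_dir: str | None = None
    hit_threshold: float = 50.0
    qc_threshold_fraction: float = 0.10
    manual_exclusions: dict = field(default_factory=dict)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    classifier_method: str = "thresholds"
    training_images_per_well: int = 1
    frame_interval_s: float = 30.0
    max_shift: int = 20
    background_percentile: float = 5.0
    n_boot: int = 5000
    n_perm: int = 5000
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Fingerprint of the analysis parameters (paths and logging are
        excluded: they do not affect the numbers)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        return cls(**d)

    def substream(self, stage: str) -> np.random.SeedSequence:
        """Deterministic per-stage seed substream derived from the global seed."""
        digest = hashlib.sha256(stage.encode()).digest()[:4]
        return np.random.SeedSequence(
            [self.seed, int.from_bytes(digest, "little")]
        )


@dataclass
class ScreenResult:
    """Bundle of one endpoint-screen analysis."""

    records: pd.DataFrame       # per-nucleus features + predicted class
    counts: pd.DataFrame        # per-well live/dead tallies
    results: list               # ProtectionResult per compound
    summary: pd.DataFrame       # tabular view of `results`
    classifier: ClassifierModel
    config_hash: str = ""


@dataclass
class TMREResult:
    """Bundle of one TMRE time-lapse analysis."""

    traces: list                # TMRETrace per well
    losses: pd.DataFrame        # well, condition, loss, auc_raw
    comparisons: pd.DataFrame   # per condition vs NMDA-only estimation stats
    config_hash: str = ""


def label_records_from_truth(
    records: pd.DataFrame, truth: pd.DataFrame, max_dist: float = 5.0
) -> pd.DataFrame:
    """Attach ground-truth classes to segmented records by centroid matching.

    Used to build a labeled training set on synthetic plates (standing in
    for the interactive annotation a screener would do).  Unmatched records
    are dropped.
    """
    out = []
    for (well, idx), grp in records.groupby(["well", "image_index"]):
        t = truth[(truth["well"] == well) & (truth["image_index"] == idx)]
        if t.empty or grp.empty:
            continue
        det = grp[["centroid_row", "centroid_col"]].to_numpy()
        tru = t[["row", "col"]].to_numpy()
        m = nuclei.match_centroids(det, tru, max_dist=max_dist)
        cls = t["cls"].to_numpy()
        labeled = grp.iloc[[d for _, d, _ in m["pairs"]]].copy()
        labeled["cls"] = [cls[ti] for ti, _, _ in m["pairs"]]
        out.append(labeled)
    if not out:
        return records.iloc[0:0].assign(cls=pd.Series(dtype=str))
    return pd.concat(out, ignore_index=True)


def segment_plate_images(
    images: dict, config: RunConfig
) -> pd.DataFrame:
    """Segment and featurize every field of every well.

    ``images`` maps well id -> list of 2-D arrays.  Returns per-nucleus
    records tagged with well and image index.
    """
    frames = []
    for well, imgs in images.items():
        for idx, img in enumerate(imgs):
            labels, _ = nuclei.segment_nuclei(img, config.segmentation)
            feats = nuclei.extract_features(labels, img)
            feats.insert(0, "well", well)
            feats.insert(1, "image_index", idx)
            frames.append(feats)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def run_screen(
    images: dict,
    layout: PlateLayout,
    config: RunConfig,
    classifier: ClassifierModel | None = None,
    truth: pd.DataFrame | None = None,
) -> ScreenResult:
    """Execute the full endpoint screen on per-well image sets.

    A classifier may be supplied (e.g. loaded from JSON); otherwise
    ``truth`` records must be given and a threshold classifier is calibrated
    on the first ``training_images_per_well`` fields of each well.  Outputs
    (summary TSV, per-nucleus TSV, config snapshot, Z-map PNG) are written
    when ``config.out_dir`` is set.  The run is deterministic for a given
    config.
    """
    missing = [w for w in layout.wells if w not in images]
    if missing:
        raise ValueError(f"layout wells without images: {missing}")

    records = segment_plate_images(images, config)
    if records.empty:
        raise ValueError("no nuclei segmented on this plate")

    if classifier is None:
        if truth is None:
            raise ValueError("need either a classifier or truth for calibration")
        train = records[records["image_index"] < config.training_images_per_well]
        labeled = label_records_from_truth(train, truth)
        classifier = nuclei.calibrate_classifier(
            labeled, method=config.classifier_method,
            seed=config.substream("classifier").entropy,
        )

    classified = nuclei.classify_nuclei(records, classifier)
    counts = nuclei.counts_by_well(classified)
    results = plate_stats.score_screen(
        counts, layout,
        hit_threshold=config.hit_threshold,
        qc_threshold_fraction=config.qc_threshold_fraction,
        manual_exclusions=config.manual_exclusions,
    )
    summary = pd.DataFrame([dataclasses.asdict(r) for r in results])
    chash = config.config_hash()
    out = ScreenResult(
        records=classified, counts=counts, results=results,
        summary=summary.assign(config_hash=chash),
        classifier=classifier, config_hash=chash,
    )
    if config.out_dir:
        _write_screen_outputs(out, layout, config)
    return out


def _write_screen_outputs(res: ScreenResult, layout: PlateLayout, config: RunConfig):
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res.summary.to_csv(out_dir / "screen_summary.tsv", sep="\t", index=False)
    res.records.to_csv(out_dir / "nuclei.tsv", sep="\t", index=False)
    res.counts.to_csv(out_dir / "well_counts.tsv", sep="\t", index=False)
    res.classifier.to_json(out_dir / "classifier.json")
    config.to_yaml(out_dir / "run_config.yaml")
    (out_dir / "config_hash.txt").write_text(res.config_hash + "\n")
    try:
        from .plotting import plot_zscore_map

        surv = res.counts.merge(layout.table[["well", "condition"]], on="well")
        surv["value"] = surv["n_live"] / surv["n_total"]
        zmap = plate_stats.zscore_map(surv[["well", "condition", "value"]])
        plot_zscore_map(zmap, out_dir / "zscore_map.png",
                        rows=layout.rows, cols=layout.cols)
    except ValueError:
        pass  # e.g. singleton condition groups: no Z map for this layout


def run_tmre(
    stacks: dict,
    config: RunConfig,
    control_condition: str = VEHICLE,
) -> TMREResult:
    """Analyze TMRE stacks grouped by condition and compare to NMDA-only.

    ``stacks`` maps condition -> list of (frames, H, W) arrays, one per
    replicate well.  Each compound condition's per-well losses are compared
    to the control (NMDA-only) condition with an unpaired mean difference,
    BCa CI and permutation test.
    """
    traces = []
    rows = []
    for cond, wells in stacks.items():
        for i, stack in enumerate(wells):
            well = f"{cond}:{i}"
            trace, _ = tmre.analyze_stack(
                stack, frame_interval_s=config.frame_interval_s, well=well,
                max_shift=config.max_shift,
                background_percentile=config.background_percentile,
            )
            traces.append(trace)
            rows.append({"well": well, "condition": cond,
                         "loss": trace.loss, "auc_raw": trace.auc_raw})
    losses = pd.DataFrame(rows)

    comps = []
    if control_condition in set(losses["condition"]):
        ctl = losses.loc[losses["condition"] == control_condition, "loss"].to_numpy()
        ss = config.substream("tmre-stats")
        others = [c for c in losses["condition"].unique() if c != control_condition]
        for cond, child in zip(others, ss.spawn(max(len(others), 1))):
            vals = losses.loc[losses["condition"] == cond, "loss"].to_numpy()
            if len(vals) >= 3 and len(ctl) >= 3:
                r = estim_stats.estimate(
                    vals, ctl, design="unpaired",
                    n_boot=config.n_boot, n_perm=config.n_perm, seed=child,
                )
                comps.append({"condition": cond, "vs": control_condition,
                              **r.to_dict()})
    comparisons = pd.DataFrame(comps)
    chash = config.config_hash()
    res = TMREResult(traces=traces, losses=losses, comparisons=comparisons,
                     config_hash=chash)
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        losses.assign(config_hash=chash).to_csv(
            out_dir / "tmre_losses.tsv", sep="\t", index=False
        )
        long = pd.concat(
            [
                pd.DataFrame({"well": t.well, "time_s": t.times, "raw": t.raw,
                              "normalized": t.normalized})
                for t in traces
            ],
            ignore_index=True,
        )
        long.to_csv(out_dir / "tmre_traces.tsv", sep="\t", index=False)
        if not comparisons.empty:
            comparisons.to_csv(out_dir / "tmre_comparisons.tsv", sep="\t",
                               index=False)
        config.to_yaml(out_dir / "run_config.yaml")
    return res
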
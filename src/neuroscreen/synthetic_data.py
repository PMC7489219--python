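"""Synthetic microscopy data with known ground truth.

Every downstream stage of the screening pipeline is exercised on data from
this module: Hoechst-like nuclear fields where dying (pyknotic) nuclei are
rendered smaller and brighter than live ones, TMRE time-lapse stacks whose
mean ROI intensity follows a delayed exponential decay toward a plateau, and
logistic concentration-response tables with known midpoints.

Nuclei are isotropic Gaussian discs, intensity = peak * exp(-r^2 / (2 s^2))
with s = radius / 2, placed by rejection sampling with a minimum center
distance of 1.5x the summed radii (100 attempts per nucleus).  Camera noise
is additive Gaussian, clipped to the 12-bit range [0, 4095] and stored in
16-bit containers, matching the screening camera's format.  Irregular
("amorphous") nuclear shapes are not modeled; the dead phenotype is encoded
by size and brightness only.

All generators are deterministic: identical seed and configuration give
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .plate_stats import PlateLayout, UNTREATED, VEHICLE
from .dose_response import hill_curve

__all__ = [
    "SimulationConfig",
    "NucleusTruth",
    "TraceModel",
    "SimulatedPlate",
    "DEFAULT_EFFECTS",
    "render_well_image",
    "simulate_plate",
    "simulate_well_counts",
    "simulate_tmre_stack",
    "trace_value",
    "simulate_dose_response",
    "write_plate",
]

MAX_ADU = 4095  # 12-bit camera full scale

#: Death probabilities matching the assay's anchor conditions: untreated
#: wells average 75.7% viability; a 10-min NMDA insult leaves ~20%.
DEFAULT_EFFECTS = {UNTREATED: 0.243, VEHICLE: 0.80}


@dataclass
class SimulationConfig:
    """Study conditions for the simulated screen.

    Geometry is a 96-well plate with the outer ring left unseeded; each well
    yields ``images_per_well`` fields of ``nuclei_per_image`` nuclei, so a
    3-well pooled condition represents ~3000 cells x 3, in line with the
    assay's sampling.  Radii are in pixels (10x objective scale: live nuclei
    ~12 px across, condensed dead nuclei roughly half that), intensities in
    ADU of a 12-bit camera.
    """

    rows: int = 8
    cols: int = 12
    exclude_border: bool = True
    images_per_well: int = 12
    nuclei_per_image: int = 250
    image_shape: tuple[int, int] = (512, 512)
    live_radius_mean: float = 6.0
    live_radius_sd: float = 1.0
    live_intensity_mean: float = 900.0
    live_intensity_sd: float = 120.0
    dead_radius_mean: float = 3.5
    dead_radius_sd: float = 0.4
    dead_intensity_mean: float = 2200.0
    dead_intensity_sd: float = 250.0
    background: float = 100.0
    noise_sd: float = 20.0
    bit_depth: int = 12
    min_separation_factor: float = 1.5
    max_attempts: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.live_radius_mean <= 0 or self.dead_radius_mean <= 0:
            raise ValueError("radii must be > 0")
        if not self.dead_radius_mean < self.live_radius_mean:
            raise ValueError("dead nuclei must be smaller than live on average")
        if not self.dead_intensity_mean > self.live_intensity_mean:
            raise ValueError("dead nuclei must be brighter than live on average")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.bit_depth != 12:
            raise ValueError("the screening camera model is 12-bit")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        d = json.loads(Path(path).read_text())
        d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


@dataclass(frozen=True)
class NucleusTruth:
    """Ground-truth record for one rendered nucleus."""

    well: str
    image_index: int
    row: float
    col: float
    radius: float
    cls: str  # "live" | "dead"


@dataclass
class TraceModel:
    """Kinetic model of a TMRE well trace (normalized scale).

    The trace sits at ``baseline`` until ``onset_s`` after NMDA application,
    then decays exponentially with rate ``rate_per_s`` toward
    ``plateau`` x baseline.  Protective compounds appear as longer onsets
    and/or smaller rates ("delayed and less pronounced" loss); untreated
    wells are flat (rate 0).  ``noise_sd`` jitters the per-frame trace value.
    """

    baseline: float = 1.0
    onset_s: float = 0.0
    rate_per_s: float = 0.0
    plateau: float = 0.0
    noise_sd: float = 0.0
    frame_interval_s: float = 30.0
    duration_s: float = 1200.0

    def __post_init__(self):
        if self.onset_s < 0 or self.rate_per_s < 0:
            raise ValueError("onset and decay rate must be >= 0")
        if not 0.0 <= self.plateau <= 1.0:
            raise ValueError("plateau must lie in [0, 1]")
        if self.duration_s < self.frame_interval_s:
            raise ValueError("duration must allow >= 2 frames")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_s + 1e-9, self.frame_interval_s)


def trace_value(model: TraceModel, t) -> np.ndarray:
    """Noise-free normalized trace F(t) of the kinetic model."""
    t = np.asarray(t, dtype=float)
    dt = np.maximum(t - model.onset_s, 0.0)
    rel = model.plateau + (1.0 - model.plateau) * np.exp(-model.rate_per_s * dt)
    return model.baseline * rel


def _place_nuclei(radii, shape, factor, max_attempts, rng):
    """Rejection-sample non-overlapping centers; radii order is placement order."""
    h, w = shape
    centers = np.empty((len(radii), 2))
    for i, r in enumerate(radii):
        margin = 2.0 * r + 1.0  # keep the rendered profile off the border
        if 2 * margin >= min(h, w):
            raise ValueError("nucleus radius too large for the image")
        placed = centers[:i]
        min_d = factor * (radii[:i] + r)
        for _ in range(max_attempts):
            cand = rng.uniform([margin, margin], [h - margin, w - margin])
            if i == 0:
                centers[0] = cand
                break
            d = np.hypot(placed[:, 0] - cand[0], placed[:, 1] - cand[1])
            if np.all(d >= min_d):
                centers[i] = cand
                break
        else:
            density = i / (h * w)
            raise RuntimeError(
                f"could not place nucleus {i + 1}/{len(radii)} after "
                f"{max_attempts} attempts; achievable density is about "
                f"{density:.2e} nuclei/px^2 for these radii"
            )
    return centers


def _render(shape, centers, radii, peaks, background, noise_sd, rng,
            profile="gaussian"):
    """Accumulate radially symmetric objects plus pedestal and camera noise.

    ``profile="gaussian"``: exp(-r^2 / 2 sigma^2), sigma = radius/2 (nuclei).
    ``profile="disc"``: flat-top supergaussian exp(-(r/radius)^8), used for
    TMRE-filled somata which image as near-uniform discs.
    """
    img = np.zeros(shape, dtype=float)
    h, w = shape
    for (cy, cx), r, peak in zip(centers, radii, peaks):
        half = int(np.ceil(2.0 * r))
        y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        if profile == "gaussian":
            sigma = r / 2.0
            img[y0:y1, x0:x1] += peak * np.exp(-d2 / (2.0 * sigma**2))
        else:
            img[y0:y1, x0:x1] += peak * np.exp(-((d2 / r**2) ** 4))
    img += background
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    return np.clip(np.rint(img), 0, MAX_ADU).astype(np.uint16)


def render_well_image(
    n_live: int,
    n_dead: int,
    config: SimulationConfig,
    seed,
    well: str = "",
    image_index: int = 0,
) -> tuple[np.ndarray, list[NucleusTruth]]:
    """Render one field with ``n_live`` live and ``n_dead`` pyknotic nuclei.

    Returns the 16-bit image (12-bit range) and one truth record per
    nucleus.  Dead nuclei draw from the smaller-radius, brighter-peak
    parameter set.  With both counts zero the image is camera noise only.
    """
    if n_live < 0 or n_dead < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    cls = np.array(["live"] * n_live + ["dead"] * n_dead)
    rng.shuffle(cls)
    is_dead = cls == "dead"
    radii = np.where(
        is_dead,
        rng.normal(config.dead_radius_mean, config.dead_radius_sd, cls.size),
        rng.normal(config.live_radius_mean, config.live_radius_sd, cls.size),
    )
    radii = np.maximum(radii, 1.0)
    peaks = np.where(
        is_dead,
        rng.normal(config.dead_intensity_mean, config.dead_intensity_sd, cls.size),
        rng.normal(config.live_intensity_mean, config.live_intensity_sd, cls.size),
    )
    peaks = np.maximum(peaks, 1.0)
    centers = _place_nuclei(
        radii, config.image_shape, config.min_separation_factor,
        config.max_attempts, rng,
    )
    img = _render(
        config.image_shape, centers, radii, peaks, config.background,
        config.noise_sd, rng,
    )
    truth = [
        NucleusTruth(well=well, image_index=image_index, row=float(c[0]),
                     col=float(c[1]), radius=float(r), cls=str(k))
        for c, r, k in zip(centers, radii, cls)
    ]
    return img, truth


@dataclass
class SimulatedPlate:
    """Images plus ground truth for a simulated screening plate."""

    images: dict  # well -> list of 2-D uint16 arrays
    truth: pd.DataFrame  # one row per nucleus
    summary: pd.DataFrame  # per-well true counts and survival
    layout: PlateLayout
    config: SimulationConfig


def simulate_plate(
    layout: PlateLayout,
    config: SimulationConfig,
    effects: dict[str, float] | None = None,
    seed=None,
    images_per_well: int | None = None,
) -> SimulatedPlate:
    """Simulate all fields of a plate with per-condition death probabilities.

    Each nucleus's class is an independent Bernoulli draw with its
    condition's death probability.  ``effects`` must cover every condition
    in the layout; it defaults to the untreated/NMDA anchor probabilities
    for layouts using only those conditions.
    """
    effects = DEFAULT_EFFECTS if effects is None else effects
    missing = sorted(
        {c for c in layout.table["condition"]} - set(effects)
    )
    if missing:
        raise ValueError(f"no death probability for conditions: {missing}")
    for cond, p in effects.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"death probability for {cond!r} not in [0, 1]")
    n_img = config.images_per_well if images_per_well is None else images_per_well
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    images: dict[str, list[np.ndarray]] = {}
    truth_rows = []
    summary_rows = []
    for well, well_ss in zip(layout.wells, root.spawn(len(layout.wells))):
        cond = layout.condition_of(well)
        p_death = effects[cond]
        well_imgs = []
        n_live_w = n_dead_w = 0
        for idx, img_ss in enumerate(well_ss.spawn(n_img)):
            rng = np.random.default_rng(img_ss)
            n_dead = int(rng.binomial(config.nuclei_per_image, p_death))
            n_live = config.nuclei_per_image - n_dead
            img, truth = render_well_image(
                n_live, n_dead, config, img_ss.spawn(1)[0],
                well=well, image_index=idx,
            )
            well_imgs.append(img)
            truth_rows.extend(asdict(t) for t in truth)
            n_live_w += n_live
            n_dead_w += n_dead
        images[well] = well_imgs
        summary_rows.append(
            {"well": well, "condition": cond, "n_live_true": n_live_w,
             "n_dead_true": n_dead_w,
             "true_survival": n_live_w / (n_live_w + n_dead_w)}
        )
    return SimulatedPlate(
        images=images,
        truth=pd.DataFrame(truth_rows),
        summary=pd.DataFrame(summary_rows),
        layout=layout,
        config=config,
    )


def simulate_well_counts(
    p_death_by_well: dict[str, float],
    n_cells_per_well: int = 3000,
    well_sd: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """Count-level well simulation (no image rendering).

    Cell-level deaths are binomial at each well's death probability;
    ``well_sd > 0`` adds a per-well random effect on the survival scale
    (truncated normal), emulating the between-well variability seen in
    primary cultures.  Used for screen-scale statistics where rendering
    every field is unnecessary.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for well, p_death in p_death_by_well.items():
        if not 0.0 <= p_death <= 1.0:
            raise ValueError(f"death probability for {well!r} not in [0, 1]")
        p_live = 1.0 - p_death
        if well_sd > 0:
            p_live = float(np.clip(rng.normal(p_live, well_sd), 1e-3, 1 - 1e-3))
        n_live = int(rng.binomial(n_cells_per_well, p_live))
        rows.append(
            {"well": well, "n_live": n_live,
             "n_dead": n_cells_per_well - n_live,
             "n_total": n_cells_per_well}
        )
    return pd.DataFrame(rows)


def simulate_tmre_stack(
    model: TraceModel,
    shape: tuple[int, int] = (192, 192),
    n_cells: int = 25,
    cell_radius: float = 6.0,
    cell_peak: float = 1500.0,
    background: float = 80.0,
    camera_noise_sd: float = 15.0,
    seed=None,
    shifts=None,
) -> tuple[np.ndarray, dict]:
    """Render a TMRE time-lapse stack for one well.

    Bright TMRE-positive somata (Gaussian discs) on a dark field; their
    amplitude follows the kinetic model's trace.  ``shifts`` optionally
    injects known integer (row, col) translations per frame for registration
    testing.  Returns the uint16 stack and a truth dict with frame times,
    the noise-free trace, per-frame applied shifts and the cell mask.
    """
    rng = np.random.default_rng(seed)
    times = model.times
    if times.size < 2:
        raise ValueError("duration/interval must yield >= 2 frames")
    f_true = trace_value(model, times)
    f_obs = f_true.copy()
    if model.noise_sd > 0:
        f_obs = f_obs + rng.normal(0.0, model.noise_sd, size=times.size)
        f_obs = np.maximum(f_obs, 0.0)

    radii = np.full(n_cells, cell_radius)
    centers = _place_nuclei(radii, shape, 1.5, 200, rng)
    peaks = rng.normal(cell_peak, 0.1 * cell_peak, size=n_cells)
    peaks = np.maximum(peaks, 1.0)

    if shifts is None:
        shifts = np.zeros((times.size, 2), dtype=int)
    else:
        shifts = np.asarray(shifts, dtype=int)
        if shifts.shape != (times.size, 2):
            raise ValueError("shifts must be (n_frames, 2)")

    frames = []
    for f, (dy, dx) in zip(f_obs, shifts):
        frames.append(
            _render(shape, centers + [dy, dx], radii, peaks * f, background,
                    camera_noise_sd, rng, profile="disc")
        )
    stack = np.stack(frames)

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for (cy, cx), r in zip(centers, radii):
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    truth = {
        "times": times,
        "trace": f_true,
        "trace_observed": f_obs,
        "shifts": shifts,
        "mask": mask,
        "centers": centers,
    }
    return stack, truth


def simulate_dose_response(
    xc50: float,
    slope: float = 1.0,
    top: float = 1.0,
    bottom: float = 0.0,
    concentrations=None,
    noise_sd: float = 0.0,
    orientation: str = "inhibition",
    seed=None,
) -> pd.DataFrame:
    """Logistic concentration-response points with Gaussian noise."""
    if concentrations is None:
        concentrations = np.logspace(-2, 2, 8) * xc50
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    resp = hill_curve(conc, top, bottom, xc50, slope, orientation)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, size=conc.size)
    return pd.DataFrame({"concentration": conc, "response": resp})


def write_plate(plate: SimulatedPlate, out_dir) -> None:
    """Persist a simulated plate: one multi-page TIFF per well, truth TSV,
    layout CSV and the config as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for well, imgs in plate.images.items():
        tifffile.imwrite(out / f"{well}.tif", np.stack(imgs))
    plate.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    plate.summary.to_csv(out / "truth_summary.tsv", sep="\t", index=False)
    plate.layout.to_csv(out / "layout.csv")
    plate.config.to_json(out / "config.json")
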
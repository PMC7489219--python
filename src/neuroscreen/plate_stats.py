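"""Plate-level screening statistics.

Converts per-well live/dead nucleus counts into survival rates, protection
scores, QC calls, hit calls, within-condition Z-score maps, and the
replicate-pooling variance analysis.

Conventions
-----------
* Survival rate S = n_live / n_total for a well or a pooled well group.
* Protection score = (S_compound - S_vehicle) / (S_untreated - S_vehicle)
  x 100, where "vehicle" means vehicle + NMDA.  Scores below 0 (toxicity)
  and above 100 are reported as-is, never clipped.
* QC: a compound's score is withheld when its pooled total cell count is
  strictly below 10% of the screen-wide average, or when the compound is on
  a manual exclusion list (e.g. colored compounds that interfere with the
  fluorescence readout).
* Hits: qc_pass and score strictly greater than the threshold (default 50%).
* Sample (n-1) standard deviations everywhere, including Z-scores.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlateLayout",
    "WellCounts",
    "ProtectionResult",
    "AssayWindowError",
    "survival_rate",
    "pool_counts",
    "protection_score",
    "qc_filter",
    "zscore_map",
    "call_hits",
    "pooling_sd_analysis",
    "score_screen",
    "UNTREATED",
    "VEHICLE",
]

UNTREATED = "untreated"
VEHICLE = "vehicle+NMDA"

_ROWS = string.ascii_uppercase


class AssayWindowError(ValueError):
    """Raised when S_untreated equals S_vehicle: the assay window collapsed."""


@dataclass(frozen=True)
class WellCounts:
    """Live/dead tallies for one well (or one pooled well group)."""

    well: str
    n_live: int
    n_dead: int

    def __post_init__(self):
        if self.n_live < 0 or self.n_dead < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_live + self.n_dead


@dataclass
class ProtectionResult:
    """Screen readout for one compound."""

    compound: str
    s_compound: float | None
    s_vehicle: float
    s_untreated: float
    score: float | None
    pooled_n_total: int
    qc_pass: bool
    qc_reason: str = ""
    hit: bool = False


@dataclass
class PlateLayout:
    """Well -> condition map for a multiwell plate.

    ``table`` has columns well, condition, compound, replicate.  By default
    the outer ring of wells is excluded (edge wells suffer evaporation and
    seeding artifacts) and carries no entries.
    """

    table: pd.DataFrame
    plate_id: str = "plate1"
    rows: int = 8
    cols: int = 12

    REQUIRED = ("well", "condition", "compound", "replicate")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"layout missing columns: {missing}")
        if self.table["well"].duplicated().any():
            dups = self.table.loc[self.table["well"].duplicated(), "well"].tolist()
            raise ValueError(f"duplicate wells in layout: {dups}")
        self.table = self.table.reset_index(drop=True)

    @property
    def wells(self) -> list[str]:
        return self.table["well"].tolist()

    def condition_of(self, well: str) -> str:
        row = self.table.loc[self.table["well"] == well]
        if row.empty:
            raise KeyError(f"well {well} not in layout")
        return str(row["condition"].iloc[0])

    def wells_for_condition(self, condition: str) -> list[str]:
        return self.table.loc[
            self.table["condition"] == condition, "well"
        ].tolist()

    @classmethod
    def from_csv(cls, path, plate_id: str = "plate1") -> "PlateLayout":
        return cls(pd.read_csv(path, dtype=str), plate_id=plate_id)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def inner_wells(cls, rows: int = 8, cols: int = 12) -> list[str]:
        """Row-major well ids with the outer ring excluded (B2..G11 on 96w)."""
        return [
            f"{_ROWS[r]}{c + 1}"
            for r in range(1, rows - 1)
            for c in range(1, cols - 1)
        ]

    @classmethod
    def build(
        cls,
        conditions: dict[str, str],
        plate_id: str = "plate1",
        rows: int = 8,
        cols: int = 12,
    ) -> "PlateLayout":
        """Layout from a well -> condition mapping.

        Condition strings of the form ``compound+NMDA:<name>`` carry the
        compound name; ``untreated`` and ``vehicle+NMDA`` map to themselves.
        """
        recs = []
        for well, cond in conditions.items():
            if cond.startswith("compound+NMDA:"):
                compound = cond.split(":", 1)[1]
            else:
                compound = cond
            recs.append(
                {"well": well, "condition": cond, "compound": compound,
                 "replicate": "1"}
            )
        return cls(pd.DataFrame(recs), plate_id=plate_id, rows=rows, cols=cols)


def well_coords(well: str) -> tuple[int, int]:
    """0-based (row, col) of a well id like 'B7'."""
    return _ROWS.index(well[0]), int(well[1:]) - 1


def _counts_frame(counts) -> pd.DataFrame:
    """Normalize WellCounts sequences or DataFrames to a counts DataFrame."""
    if isinstance(counts, pd.DataFrame):
        df = counts.copy()
        if "n_total" not in df.columns:
            df["n_total"] = df["n_live"] + df["n_dead"]
        return df
    rows = [
        {"well": c.well, "n_live": c.n_live, "n_dead": c.n_dead,
         "n_total": c.n_total}
        for c in counts
    ]
    return pd.DataFrame(rows)


def survival_rate(n_live, n_total=None) -> float:
    """Fraction of living cells: S = n_live / n_total.

    Accepts either a :class:`WellCounts` or the two counts.  A zero total is
    a hard error (no cells counted), deliberately distinct from the QC
    low-count exclusion which withholds a score with a reason.
    """
    if isinstance(n_live, WellCounts):
        counts = n_live
        n_live, n_total = counts.n_live, counts.n_total
    if n_total is None:
        raise TypeError("survival_rate needs (n_live, n_total) or a WellCounts")
    if n_total <= 0:
        raise ZeroDivisionError("survival rate undefined: total cell count is 0")
    s = n_live / n_total
    if not 0.0 <= s <= 1.0:
        raise ValueError("n_live must lie in [0, n_total]")
    return float(s)


def pool_counts(counts, group_size: int) -> pd.DataFrame:
    """Sum counts over disjoint consecutive groups of ``group_size`` wells.

    Wells are grouped in the given (acquisition) order; a trailing remainder
    smaller than the group is dropped.  Pooled survival therefore equals the
    count-weighted mean of member survivals.
    """
    df = _counts_frame(counts)
    n = len(df)
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if group_size > n:
        raise ValueError(f"group_size {group_size} exceeds {n} wells")
    n_groups = n // group_size
    df = df.iloc[: n_groups * group_size]
    group = np.repeat(np.arange(n_groups), group_size)
    pooled = (
        df.assign(_g=group)
        .groupby("_g", sort=True)
        .agg(
            well=("well", lambda w: "+".join(w)),
            n_live=("n_live", "sum"),
            n_dead=("n_dead", "sum"),
            n_total=("n_total", "sum"),
        )
        .reset_index(drop=True)
    )
    return pooled


def protection_score(s_compound: float, s_vehicle: float, s_untreated: float) -> float:
    """Percent protection relative to the assay window.

    score = (S_compound - S_vehicle) / (S_untreated - S_vehicle) x 100.
    100 means full rescue to untreated survival, 0 means no effect; values
    outside [0, 100] are meaningful (toxicity / better-than-untreated) and
    are returned unclipped.
    """
    window = s_untreated - s_vehicle
    if window == 0:
        raise AssayWindowError(
            "assay window collapsed: S_untreated equals S_vehicle"
        )
    return float((s_compound - s_vehicle) / window * 100.0)


def qc_filter(
    pooled_totals: dict[str, int] | pd.Series,
    threshold_fraction: float = 0.10,
    manual_exclusions: dict[str, str] | None = None,
    screen_average: float | None = None,
) -> pd.DataFrame:
    """Low-count and manual-exclusion QC over per-compound pooled totals.

    A compound fails when its pooled total cell count is strictly below
    ``threshold_fraction`` of the screen-wide average total (computed across
    all compounds in this invocation unless ``screen_average`` is given), or
    when it appears in ``manual_exclusions`` (reason string reported).
    """
    totals = pd.Series(pooled_totals, dtype=float)
    if screen_average is None:
        screen_average = float(totals.mean())
    if screen_average <= 0:
        raise ValueError("screen-wide average cell count must be > 0")
    manual_exclusions = manual_exclusions or {}
    records = []
    cutoff = threshold_fraction * screen_average
    for compound, total in totals.items():
        if compound in manual_exclusions:
            records.append(
                {"compound": compound, "qc_pass": False,
                 "qc_reason": manual_exclusions[compound]}
            )
        elif total < cutoff:  # strict: exactly 10% of the average passes
            records.append(
                {"compound": compound, "qc_pass": False,
                 "qc_reason": (
                     f"low cell count ({total:.0f} < {threshold_fraction:.0%}"
                     f" of screen average {screen_average:.0f})"
                 )}
            )
        else:
            records.append({"compound": compound, "qc_pass": True, "qc_reason": ""})
    return pd.DataFrame(records)


def zscore_map(values: pd.DataFrame) -> pd.DataFrame:
    """Within-condition Z-scores of per-well values.

    ``values`` has columns well, condition, value.  Z = (x - group mean) /
    group sample SD, computed independently per condition so systematic
    differences between treated and control wells do not masquerade as
    positional effects.  Adds 0-based plate coordinates for heatmap
    rendering.
    """
    for c in ("well", "condition", "value"):
        if c not in values.columns:
            raise ValueError(f"missing column {c!r}")
    out = values.copy()
    out["z"] = np.nan
    for cond, grp in out.groupby("condition"):
        if len(grp) < 2:
            raise ValueError(f"condition {cond!r} has < 2 wells")
        sd = grp["value"].std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero within-group SD for condition {cond!r}")
        out.loc[grp.index, "z"] = (grp["value"] - grp["value"].mean()) / sd
    coords = out["well"].map(well_coords)
    out["plate_row"] = [rc[0] for rc in coords]
    out["plate_col"] = [rc[1] for rc in coords]
    return out


def call_hits(results: list[ProtectionResult], threshold: float = 50.0) -> list[ProtectionResult]:
    """Flag hits: qc_pass and score strictly above ``threshold`` percent."""
    for r in results:
        r.hit = bool(r.qc_pass and r.score is not None and r.score > threshold)
    return [r for r in results if r.hit]


def pooling_sd_analysis(counts, group_sizes=(1, 2, 3, 5)) -> pd.DataFrame:
    """SD of pooled survival as a function of pooling group size.

    For each k, wells are pooled in disjoint consecutive groups of k and the
    sample SD of the pooled survival values is reported.  With purely
    binomial (cell-level) noise the SD falls as 1/sqrt(k); genuine well-level
    variability makes the decline shallower.
    """
    df = _counts_frame(counts)
    rows = []
    for k in group_sizes:
        pooled = pool_counts(df, k)
        surv = pooled["n_live"] / pooled["n_total"]
        rows.append({"k": k, "n_groups": len(pooled),
                     "sd": float(surv.std(ddof=1))})
    return pd.DataFrame(rows)


def score_screen(
    counts: pd.DataFrame,
    layout: PlateLayout,
    hit_threshold: float = 50.0,
    qc_threshold_fraction: float = 0.10,
    manual_exclusions: dict[str, str] | None = None,
) -> list[ProtectionResult]:
    """Full screen scoring: pool per compound, QC, score, call hits.

    ``counts`` has one row per well (well, n_live, n_dead).  Wells are
    grouped by the layout's compound; the vehicle+NMDA and untreated
    condition groups anchor the protection-score window.  Compounds failing
    QC get ``score=None``.
    """
    df = _counts_frame(counts).merge(
        layout.table[["well", "condition", "compound"]], on="well", how="inner"
    )
    missing = set(layout.wells) - set(df["well"])
    if missing:
        raise ValueError(f"layout wells without counts: {sorted(missing)}")

    pooled = df.groupby("compound", sort=False).agg(
        condition=("condition", "first"),
        n_live=("n_live", "sum"),
        n_total=("n_total", "sum"),
    )
    for anchor in (UNTREATED, VEHICLE):
        if anchor not in pooled.index:
            raise ValueError(f"screen requires a {anchor!r} condition group")
    s_unt = survival_rate(int(pooled.loc[UNTREATED, "n_live"]),
                          int(pooled.loc[UNTREATED, "n_total"]))
    s_veh = survival_rate(int(pooled.loc[VEHICLE, "n_live"]),
                          int(pooled.loc[VEHICLE, "n_total"]))

    compounds = pooled.drop(index=[UNTREATED, VEHICLE])
    qc = qc_filter(
        compounds["n_total"],
        threshold_fraction=qc_threshold_fraction,
        manual_exclusions=manual_exclusions,
    ).set_index("compound")

    results = []
    for compound, row in compounds.iterrows():
        passed = bool(qc.loc[compound, "qc_pass"])
        reason = str(qc.loc[compound, "qc_reason"])
        if passed and row["n_total"] > 0:
            s_c = survival_rate(int(row["n_live"]), int(row["n_total"]))
            score = protection_score(s_c, s_veh, s_unt)
        else:
            s_c, score = None, None
        results.append(
            ProtectionResult(
                compound=str(compound), s_compound=s_c, s_vehicle=s_veh,
                s_untreated=s_unt, score=score,
                pooled_n_total=int(row["n_total"]),
                qc_pass=passed, qc_reason=reason,
            )
        )
    call_hits(results, threshold=hit_threshold)
    return results
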
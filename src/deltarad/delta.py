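"""Weekly aggregation and ratio-to-baseline delta features.

Daily feature values are averaged over fixed five-fraction blocks (treatment
weeks); the delta for a single week is the weekly mean divided by the
fraction-1 value, and the delta for a grouped window is the unweighted mean of
the window's weekly means divided by the fraction-1 value:

    Xbar[i, w] = (1 / N_w) * sum_f X[i, w, f]
    delta[i, w] = Xbar[i, w] / X[i, 1]
    delta[i, W] = (1 / |W|) * sum_{w in W} Xbar[i, w] / X[i, 1]

Week 1's mean includes fraction 1 itself, so delta[i, 1] is generally not 1.
Ratios are undefined when the baseline is (near) zero; such patient-feature
cells are excluded with a logged reason rather than clipped, because
small-denominator ratios are numerically unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .preprocess import ParameterError

BASELINE_EPS = 1e-12


@dataclass(frozen=True)
class WindowSpec:
    """A set of treatment weeks aggregated before the baseline ratio."""

    weeks: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.weeks:
            raise ParameterError("weeks: window must be non-empty")
        if len(set(self.weeks)) != len(self.weeks):
            raise ParameterError("weeks: duplicate week in window")
        if not self.label:
            object.__setattr__(self, "label", format_window_label(self.weeks))

    @classmethod
    def parse(cls, text: str) -> "WindowSpec":
        """Parse "2" or "1-4" (inclusive week range)."""
        text = text.strip()
        if "-" in text:
            lo, hi = (int(t) for t in text.split("-", 1))
            if hi < lo:
                raise ParameterError(f"windows: bad range {text!r}")
            return cls(tuple(range(lo, hi + 1)))
        return cls((int(text),))


def format_window_label(weeks: tuple[int, ...]) -> str:
    ws = sorted(weeks)
    if len(ws) == 1:
        return f"Week {ws[0]}"
    if ws == list(range(ws[0], ws[-1] + 1)):
        return f"Weeks {ws[0]}-{ws[-1]}"
    return "Weeks " + ",".join(str(w) for w in ws)


@dataclass
class DeltaTable:
    """Wide per-window delta matrix (rows = patients, columns = features)."""

    window: WindowSpec
    data: pd.DataFrame
    exclusions: list[dict] = field(default_factory=list)


def _validate_fraction_table(t: pd.DataFrame) -> None:
    required = {"patient_id", "fraction", "week", "feature_name", "value"}
    missing = required - set(t.columns)
    if missing:
        raise ParameterError(f"fraction table: missing columns {sorted(missing)}")
    if t.duplicated(["patient_id", "feature_name", "fraction"]).any():
        raise ParameterError("fraction table: duplicate (patient, feature, fraction) records")


def weekly_mean(t: pd.DataFrame, min_fractions: int = 3) -> pd.DataFrame:
    """Weekly means per (patient, feature, week).

    Returns a frame with columns patient_id, feature_name, week, value,
    n_fractions.  Weeks with fewer than ``min_fractions`` usable fractions are
    dropped (they become missing cells downstream).
    """
    _validate_fraction_table(t)
    usable = t.dropna(subset=["value"])
    g = (usable.groupby(["patient_id", "feature_name", "week"], sort=True)["value"]
         .agg(value="mean", n_fractions="count").reset_index())
    return g[g["n_fractions"] >= min_fractions].reset_index(drop=True)


def baseline_values(t: pd.DataFrame) -> pd.DataFrame:
    """Fraction-1 value per (patient, feature) — the delta denominator."""
    _validate_fraction_table(t)
    b = t[t["fraction"] == 1][["patient_id", "feature_name", "value"]]
    if b.empty:
        raise ParameterError("fraction table: no fraction-1 baseline records")
    return b.rename(columns={"value": "baseline"}).reset_index(drop=True)


def delta_grouped(weekly: pd.DataFrame, baseline: pd.DataFrame,
                  window: WindowSpec, eps: float = BASELINE_EPS) -> DeltaTable:
    """Ratio-to-baseline delta for a grouped window of weeks.

    Weekly means are averaged with equal week weights (not pooled over
    fractions) before dividing by the fraction-1 baseline.  Patients missing
    any week of the window, and patient-feature cells with |baseline| < eps,
    are excluded with a logged reason.
    """
    weeks = set(window.weeks)
    avail = set(weekly["week"].unique())
    if not weeks <= avail:
        raise ParameterError(
            f"windows: window {window.label!r} references absent weeks {sorted(weeks - avail)}")
    exclusions: list[dict] = []

    sub = weekly[weekly["week"].isin(weeks)]
    counts = sub.groupby(["patient_id", "feature_name"])["week"].nunique()
    win_mean = (sub.groupby(["patient_id", "feature_name"])["value"].mean()
                .to_frame("win_mean").reset_index())
    win_mean = win_mean.merge(counts.rename("n_weeks").reset_index(),
                              on=["patient_id", "feature_name"])
    incomplete = win_mean["n_weeks"] < len(weeks)
    for _, row in win_mean[incomplete].iterrows():
        exclusions.append({"stage": "delta", "window": window.label,
                           "patient_id": row["patient_id"],
                           "feature_name": row["feature_name"],
                           "reason": "missing week in window"})
    win_mean = win_mean[~incomplete]

    merged = win_mean.merge(baseline, on=["patient_id", "feature_name"], how="left")
    bad = merged["baseline"].isna() | (merged["baseline"].abs() < eps)
    for _, row in merged[bad].iterrows():
        exclusions.append({"stage": "delta", "window": window.label,
                           "patient_id": row["patient_id"],
                           "feature_name": row["feature_name"],
                           "reason": "baseline below epsilon (ratio instability)"})
    merged = merged[~bad]
    merged = merged.assign(delta=merged["win_mean"] / merged["baseline"])

    wide = merged.pivot(index="patient_id", columns="feature_name", values="delta")
    # keep the first-appearance (registry) feature order of the baseline table
    order = [f for f in baseline["feature_name"].unique() if f in wide.columns]
    wide = wide[order]
    wide.columns.name = None
    return DeltaTable(window=window, data=wide, exclusions=exclusions)


def delta_single_week(weekly: pd.DataFrame, baseline: pd.DataFrame, week: int,
                      eps: float = BASELINE_EPS) -> DeltaTable:
    """Single-week delta; identical to a grouped window of one week."""
    return delta_grouped(weekly, baseline, WindowSpec((week,)), eps=eps)
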
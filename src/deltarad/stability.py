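"""Feature-stability diagnostics on weekly delta trajectories.

For every feature the patients-by-weeks matrix of single-week deltas is
summarized by three complementary measures:

* an ICC-like index — the one-way random-effects intraclass correlation
  ICC(1,1) = (MSB - MSW) / (MSB + (k - 1) MSW), clipped to [0, 1], where MSB
  and MSW are the between- and within-patient mean squares over k weeks;
* the mean within-patient standard deviation across weeks; and
* the mean within-patient coefficient of variation (SD / |mean|), with
  near-zero patient means excluded rather than producing unbounded values.

These are diagnostics only: no feature is excluded on stability grounds, and
the selection / modeling stages run identically whether or not this module is
invoked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .delta import DeltaTable
from .preprocess import ParameterError

CV_MEAN_EPS = 1e-8


def icc_oneway(matrix: np.ndarray) -> float:
    """ICC(1,1) on an n_subjects x k_timepoints matrix, clipped to [0, 1]."""
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ParameterError("stability: need >= 2 patients and >= 2 timepoints")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    msb = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msw = ((m - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return 0.0
    return float(np.clip((msb - msw) / denom, 0.0, 1.0))


def compute_stability(weekly_deltas: list[DeltaTable],
                      max_invalid_frac: float = 0.5) -> pd.DataFrame:
    """Stability report from single-week delta tables (one per week).

    Returns one row per feature with icc_like, mean within-patient CV and SD,
    and the patient / timepoint counts used.  Features invalid (missing) for
    more than ``max_invalid_frac`` of patients are reported as missing.
    """
    if len(weekly_deltas) < 2:
        raise ParameterError("stability: need >= 2 weekly timepoints")
    wide = {dt.window.weeks[0]: dt.data for dt in weekly_deltas}
    features = list(next(iter(wide.values())).columns)
    all_patients = sorted(set().union(*[set(d.index) for d in wide.values()]))

    rows = []
    for feat in features:
        mat = pd.DataFrame(
            {w: d[feat] if feat in d.columns else np.nan for w, d in wide.items()},
            index=all_patients).sort_index(axis=1)
        complete = mat.dropna(axis=0)
        n_invalid = len(all_patients) - len(complete)
        if len(complete) < 2 or n_invalid > max_invalid_frac * len(all_patients):
            rows.append({"feature_name": feat, "icc_like": np.nan,
                         "mean_within_patient_cv": np.nan,
                         "mean_within_patient_sd": np.nan,
                         "n_patients": len(complete), "n_timepoints": mat.shape[1]})
            continue
        m = complete.to_numpy()
        sd = m.std(axis=1, ddof=1)
        means = m.mean(axis=1)
        ok = np.abs(means) >= CV_MEAN_EPS
        cv = float((sd[ok] / np.abs(means[ok])).mean()) if ok.any() else np.nan
        rows.append({"feature_name": feat,
                     "icc_like": icc_oneway(m),
                     "mean_within_patient_cv": cv,
                     "mean_within_patient_sd": float(sd.mean()),
                     "n_patients": len(complete),
                     "n_timepoints": mat.shape[1]})
    return pd.DataFrame(rows)
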
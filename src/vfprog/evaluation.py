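"""Evaluation framework for progression-detection methods.

The full series of an eye (all ten exams, VF1-10) serves as the surrogate
truth; each truncated series (VF1-3 ... VF1-9) is re-analysed and compared
against it:

- PBP (proportion both progressing) — of eyes called significant on the
  full series, the fraction also called on the truncation: a true-positive
  surrogate.
- PBNP (proportion both not progressing) — of eyes *not* called on the full
  series, the fraction also not called on the truncation: a true-negative
  surrogate.
- PIP (proportion inconsistent progression) — of eyes called on the
  truncation, the fraction not called on the full series: a false-positive
  surrogate.

Alongside: mean squared error of predicting the final exam's mTD from each
truncation, exact paired Wilcoxon comparisons of per-truncation metric
curves, and Kaplan-Meier time-to-first-detection with the logrank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats


@dataclass
class ProgressionCalls:
    """Significance flags of one method: full series plus each truncation."""

    full: np.ndarray  # (n_eyes,) bool, calls on VF1-10
    truncated: dict[int, np.ndarray]  # k -> (n_eyes,) bool, calls on VF1-k

    def __post_init__(self) -> None:
        self.full = np.asarray(self.full, dtype=bool)
        self.truncated = {
            int(k): np.asarray(v, dtype=bool) for k, v in self.truncated.items()
        }
        for k, v in self.truncated.items():
            if v.shape != self.full.shape:
                raise ValueError(f"truncation {k} has {v.shape[0]} eyes, full has {self.full.shape[0]}")


def consistency(calls: ProgressionCalls) -> pd.DataFrame:
    """PBP/PBNP/PIP per truncation length, with numerators and denominators.

    An undefined proportion (denominator zero) is reported as NaN.
    """
    if calls.full.size == 0:
        raise ValueError("no eyes to evaluate")
    rows = []
    for k in sorted(calls.truncated):
        trunc = calls.truncated[k]
        full = calls.full
        n_full = int(full.sum())
        n_not_full = int((~full).sum())
        n_trunc = int(trunc.sum())
        pbp_num = int((full & trunc).sum())
        pbnp_num = int((~full & ~trunc).sum())
        pip_num = int((trunc & ~full).sum())
        rows.append(
            {
                "k": k,
                "pbp": pbp_num / n_full if n_full else np.nan,
                "pbp_num": pbp_num,
                "pbp_den": n_full,
                "pbnp": pbnp_num / n_not_full if n_not_full else np.nan,
                "pbnp_num": pbnp_num,
                "pbnp_den": n_not_full,
                "pip": pip_num / n_trunc if n_trunc else np.nan,
                "pip_num": pip_num,
                "pip_den": n_trunc,
            }
        )
    return pd.DataFrame(rows).set_index("k")


def prediction_errors(
    observed: Sequence[float] | np.ndarray,
    predictions: Mapping[int, Sequence[float] | np.ndarray],
) -> dict[int, float]:
    """Mean squared error (dB²) of final-exam mTD predictions per truncation."""
    observed = np.asarray(observed, dtype=float)
    out = {}
    for k in sorted(predictions):
        pred = np.asarray(predictions[k], dtype=float)
        if pred.shape != observed.shape:
            raise ValueError(f"truncation {k}: {pred.shape[0]} predictions for {observed.shape[0]} eyes")
        out[int(k)] = float(np.mean((pred - observed) ** 2))
    return out


def paired_wilcoxon(a, b) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value on paired metric curves.

    Zero differences are dropped (standard convention); if every pair is
    tied the comparison is degenerate and 1.0 is returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    if np.all(d == 0):
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method="exact")
    return float(res.pvalue)


@dataclass
class SurvivalRecord:
    """Time (exam count) to first significant call for one eye."""

    eye_index: int
    time: int  # exam count at detection, or end of series if censored
    event: bool  # True if detected, False if censored

    def __post_init__(self) -> None:
        if not 3 <= self.time <= 10:
            raise ValueError(f"detection/censoring time must be in 3..10, got {self.time}")


def detection_survival(
    calls: ProgressionCalls, full_length: int = 10
) -> list[SurvivalRecord]:
    """First truncation length at which each eye is called significant.

    The scan includes the full series as the final opportunity; an eye never
    called is censored at ``full_length`` exams.  A non-monotone call
    pattern (significant, then not) counts at the *first* significant call.
    """
    lengths = sorted(calls.truncated)
    n = calls.full.shape[0]
    records = []
    for i in range(n):
        time, event = full_length, bool(calls.full[i])
        for k in lengths:
            if calls.truncated[k][i]:
                time, event = k, True
                break
        records.append(SurvivalRecord(eye_index=i, time=time, event=event))
    return records


def _to_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=bool)
    return t, e


def kaplan_meier(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit estimate of remaining-undetected probability.

    Returns a table with columns ``time`` and ``survival`` (the step values
    at each observed time).
    """
    if not records:
        raise ValueError("no records")
    t, e = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()})


def logrank(
    records_a: Sequence[SurvivalRecord], records_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Logrank comparison of two detection-time samples.

    Returns the chi-square statistic (1 df, standard hypergeometric
    variance) and its p-value.
    """
    ta, ea = _to_arrays(records_a)
    tb, eb = _to_arrays(records_b)
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)
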
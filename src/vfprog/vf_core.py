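"""Core data model for Humphrey 24-2 visual fields.

A visual field (VF) exam measures differential light sensitivity at a fixed
grid of test locations.  The quantities handled here are *total deviation*
(TD) values: per-location sensitivity minus the age-corrected normal value,
in decibels.  The 24-2 test pattern has 54 locations; the two locations
falling on the physiological blind spot are excluded throughout, so every
field is a vector of 52 TD values.

Coordinate convention
---------------------
Right-eye (OD) orientation with nasal field at positive ``x`` (degrees of
visual angle), superior at positive ``y``.  Points are ordered in printout
scan order: rows from superior to inferior, left to right within a row.
Left-eye fields are mirrored about the vertical midline at ingest
(:func:`mirror_td`), so all stored vectors share one layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_POINTS = 52
BLIND_SPOT = ((15, 3), (15, -3))

TD_MIN = -38.0  # deepest measurable total deviation, dB
TD_MAX = 5.0


def _build_grid_24_2() -> tuple[np.ndarray, np.ndarray]:
    rows = [
        (21, range(-9, 10, 6)),
        (15, range(-15, 16, 6)),
        (9, range(-21, 22, 6)),
        (3, range(-21, 28, 6)),
        (-3, range(-21, 28, 6)),
        (-9, range(-21, 22, 6)),
        (-15, range(-15, 16, 6)),
        (-21, range(-9, 10, 6)),
    ]
    xs, ys = [], []
    for y, xr in rows:
        for x in xr:
            if (x, y) in BLIND_SPOT:
                continue
            xs.append(x)
            ys.append(y)
    return np.array(xs, dtype=float), np.array(ys, dtype=float)


def _build_grid_30_2() -> tuple[np.ndarray, np.ndarray]:
    rows = [
        (27, range(-9, 10, 6)),
        (21, range(-15, 16, 6)),
        (15, range(-21, 22, 6)),
        (9, range(-27, 28, 6)),
        (3, range(-27, 28, 6)),
        (-3, range(-27, 28, 6)),
        (-9, range(-27, 28, 6)),
        (-15, range(-21, 22, 6)),
        (-21, range(-15, 16, 6)),
        (-27, range(-9, 10, 6)),
    ]
    xs, ys = [], []
    for y, xr in rows:
        for x in xr:
            if (x, y) in BLIND_SPOT:
                continue
            xs.append(x)
            ys.append(y)
    return np.array(xs, dtype=float), np.array(ys, dtype=float)


#: 24-2 test-point coordinates in scan order (blind spot excluded), degrees.
X_DEG, Y_DEG = _build_grid_24_2()

#: 30-2 test-point coordinates in scan order (blind spot excluded), degrees.
X30_DEG, Y30_DEG = _build_grid_30_2()

N_POINTS_30_2 = len(X30_DEG)  # 74


def point_grid() -> pd.DataFrame:
    """The 24-2 grid as a table: ``point_index``, ``x_deg``, ``y_deg``."""
    return pd.DataFrame(
        {"point_index": np.arange(N_POINTS), "x_deg": X_DEG, "y_deg": Y_DEG}
    )


def _overlap_index_30_2() -> np.ndarray:
    """For each 24-2 point, the index of the matching 30-2 location."""
    lookup = {(x, y): i for i, (x, y) in enumerate(zip(X30_DEG, Y30_DEG))}
    return np.array([lookup[(x, y)] for x, y in zip(X_DEG, Y_DEG)], dtype=int)


_OVERLAP_30_2 = _overlap_index_30_2()


@dataclass
class VisualField:
    """One VF exam: 52 TD values plus reliability indices and a timestamp.

    Parameters
    ----------
    td
        Total deviation at the 52 grid points, dB.  Must be finite.
    t
        Time since the eye's baseline exam, decimal years (``>= 0``).
    fl, fp, fn
        Fixation-loss, false-positive and false-negative rates, percent.
    """

    td: np.ndarray
    t: float = 0.0
    fl: float = 0.0
    fp: float = 0.0
    fn: float = 0.0

    def __post_init__(self) -> None:
        td = np.asarray(self.td, dtype=float)
        if td.shape != (N_POINTS,):
            raise ValueError(
                f"expected {N_POINTS} total-deviation values, got shape {td.shape}"
            )
        if not np.all(np.isfinite(td)):
            raise ValueError("total-deviation values must be finite")
        if not (np.isfinite(self.t) and self.t >= 0):
            raise ValueError(f"time since baseline must be >= 0, got {self.t}")
        self.td = td

    @property
    def mtd(self) -> float:
        return compute_mtd(self)


@dataclass
class VFSeries:
    """Longitudinal series of exams of one eye, sorted by time.

    Exams must have strictly increasing ``t``.  A series may be empty after
    reliability filtering; most analyses require a minimum length and check
    it themselves.
    """

    eye_id: str
    exams: list[VisualField] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.times
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(f"exam times of eye {self.eye_id!r} must strictly increase")

    def __len__(self) -> int:
        return len(self.exams)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.t for e in self.exams], dtype=float)

    @property
    def td_matrix(self) -> np.ndarray:
        """Exams stacked as an ``(n_exams, 52)`` array."""
        if not self.exams:
            return np.empty((0, N_POINTS))
        return np.stack([e.td for e in self.exams])

    @property
    def mtd(self) -> np.ndarray:
        """Per-exam mean total deviation, dB."""
        return np.array([compute_mtd(e) for e in self.exams])

    def truncate(self, k: int) -> "VFSeries":
        """The sub-series of the first ``k`` exams (VF1..VFk)."""
        if not 1 <= k <= len(self.exams):
            raise ValueError(f"cannot truncate series of length {len(self.exams)} to {k}")
        return VFSeries(self.eye_id, self.exams[:k])


@dataclass
class ReliabilityCriteria:
    """Upper bounds (exclusive) on FL/FP/FN percentages for a usable exam."""

    max_fl: float = 33.0
    max_fp: float = 33.0
    max_fn: float = 33.0

    def __post_init__(self) -> None:
        for name in ("max_fl", "max_fp", "max_fn"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must be in (0, 100], got {v}")

    def accepts(self, field: VisualField) -> bool:
        return (
            field.fl < self.max_fl
            and field.fp < self.max_fp
            and field.fn < self.max_fn
        )


def compute_mtd(field: VisualField | np.ndarray) -> float:
    """Mean total deviation: the arithmetic mean of the 52 TD values, dB."""
    td = field.td if isinstance(field, VisualField) else np.asarray(field, dtype=float)
    if td.shape != (N_POINTS,):
        raise ValueError(f"expected {N_POINTS} values, got shape {td.shape}")
    if not np.all(np.isfinite(td)):
        raise ValueError("total-deviation values must be finite")
    return float(td.mean())


def filter_reliable(
    series: VFSeries, criteria: ReliabilityCriteria | None = None
) -> VFSeries:
    """Drop exams failing the reliability criteria (strict ``<`` thresholds).

    Order is preserved; the result may be empty.
    """
    criteria = criteria or ReliabilityCriteria()
    return VFSeries(series.eye_id, [e for e in series.exams if criteria.accepts(e)])


def reduce_30_2(td74: Sequence[float] | np.ndarray) -> np.ndarray:
    """Reduce a 30-2 field to the 52 locations shared with the 24-2 pattern.

    Parameters
    ----------
    td74
        TD values at the 74 locations of the 30-2 pattern (76 minus the two
        blind-spot points), in scan order matching ``X30_DEG``/``Y30_DEG``.

    Returns
    -------
    The 52 values at locations shared with 24-2, in 24-2 grid order.
    """
    td74 = np.asarray(td74, dtype=float)
    if td74.shape != (N_POINTS_30_2,):
        raise ValueError(
            f"expected {N_POINTS_30_2} values for a 30-2 field, got shape {td74.shape}"
        )
    return td74[_OVERLAP_30_2]


def mirror_td(td: Sequence[float] | np.ndarray) -> np.ndarray:
    """Mirror a left-eye field about the vertical midline into OD layout.

    A left-eye chart in its own scan order is the x-mirror of the right-eye
    chart, so mirroring amounts to reversing the values within each row.
    """
    td = np.asarray(td, dtype=float)
    if td.shape != (N_POINTS,):
        raise ValueError(f"expected {N_POINTS} values, got shape {td.shape}")
    out = np.empty_like(td)
    for y in np.unique(Y_DEG):
        idx = np.flatnonzero(Y_DEG == y)
        out[idx] = td[idx[::-1]]
    return out


# ---------------------------------------------------------------------------
# CSV persistence
# ---------------------------------------------------------------------------

TD_COLUMNS = [f"td_{i:02d}" for i in range(1, N_POINTS + 1)]
CSV_COLUMNS = ["eye_id", "t_years", *TD_COLUMNS, "fl", "fp", "fn"]


def cohort_to_frame(cohort: Iterable[VFSeries]) -> pd.DataFrame:
    rows = []
    for series in cohort:
        for exam in series.exams:
            rows.append(
                [series.eye_id, exam.t, *exam.td, exam.fl, exam.fp, exam.fn]
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_cohort_csv(cohort: Iterable[VFSeries], path) -> None:
    """Write a cohort to CSV: one row per exam, header required on read."""
    cohort_to_frame(cohort).to_csv(path, index=False, float_format="%.17g")


def frame_to_cohort(df: pd.DataFrame) -> list[VFSeries]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    numeric_cols = [c for c in CSV_COLUMNS if c != "eye_id"]
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric value in column {col!r} at row {row}")
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ValueError(f"missing value in column {col!r} at row {row}")
        df = df.assign(**{col: converted})
    dup = df.duplicated(subset=["eye_id", "t_years"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"duplicate (eye_id, t_years) at row {row}")
    cohort = []
    for eye_id, grp in df.groupby("eye_id", sort=False):
        grp = grp.sort_values("t_years")
        exams = [
            VisualField(
                td=row[TD_COLUMNS].to_numpy(dtype=float),
                t=float(row["t_years"]),
                fl=float(row["fl"]),
                fp=float(row["fp"]),
                fn=float(row["fn"]),
            )
            for _, row in grp.iterrows()
        ]
        cohort.append(VFSeries(str(eye_id), exams))
    return cohort


def read_cohort_csv(path) -> list[VFSeries]:
    """Read a cohort CSV; rows are re-sorted by ``t_years`` within each eye."""
    df = pd.read_csv(path, dtype={"eye_id": str})
    return frame_to_cohort(df)
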
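"""Synthetic longitudinal glaucomatous visual-field cohorts.

Emulates the statistical structure of clinical progression series so that
denoising and trend analyses can be trained and evaluated without patient
data: spatially structured defects (arcuate bundles, nasal step, diffuse
loss), linear eye-level progression with configurable mean/SD, and
sensitivity-dependent (heteroscedastic) test-retest noise — damaged
locations fluctuate more than healthy ones, which is what makes
reconstruction-error weighting informative downstream.

Randomness is split into named substreams (defect structure, measurement
noise, reliability indices) so that changing one leaves the others
bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .vf_core import N_POINTS, TD_MAX, TD_MIN, VFSeries, VisualField, X_DEG, Y_DEG

# substream tags: (seed, tag, eye_index) feeds numpy's SeedSequence
_STREAM_STRUCTURE = 11
_STREAM_NOISE = 22
_STREAM_RELIABILITY = 33

#: reliability-index means/SDs (percent) the generator targets, truncated to [0, 100]
RELIABILITY_MEANS = {"fl": 4.9, "fp": 3.7, "fn": 2.9}
RELIABILITY_SDS = {"fl": 6.4, "fp": 5.4, "fn": 4.5}


@dataclass
class CohortConfig:
    """Population parameters of a simulated cohort.

    Defaults reproduce a moderately damaged open-angle-glaucoma population:
    baseline mean total deviation -6.9 +/- 6.3 dB, progression
    -0.26 +/- 0.46 dB/year, ten exams spanning roughly 5.4 years.
    """

    n_eyes: int = 100
    n_exams: int = 10
    interval_years: float = 0.6
    baseline_mtd_mean: float = -6.9
    baseline_mtd_sd: float = 6.3
    slope_mean: float = -0.26
    slope_sd: float = 0.46
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exams < 2:
            raise ValueError("n_exams must be >= 2")
        if self.baseline_mtd_sd < 0 or self.slope_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        if self.interval_years <= 0:
            raise ValueError("interval_years must be > 0")


@dataclass
class NoiseModel:
    """Damage-dependent, exam-varying measurement noise.

    Three components, mirroring the main sources of perimetric test-retest
    variability:

    - a Gaussian per-point component whose SD grows with true damage depth
      and saturates: ``sd = min(sd_cap, sd_floor + sd_slope * max(0, -td_true))``;
    - an exam-level reliability factor (lognormal, median 1, log-SD
      ``exam_scale_sd``) multiplying every SD of that visit — attention and
      fatigue differ between visits, so some exams are globally noisier;
    - a whole-field shift per exam (``exam_shift_sd``, dB): the classic
      long-term fluctuation — on a bad day the entire field reads a little
      depressed, on a good day a little better;
    - sparse response errors, spatially inconsistent with the rest of the
      field: with per-point probability ``fp_lapse_rate`` (scaled by the
      exam factor) a damaged point (true TD below -10 dB) reads spuriously
      near-normal — the "trigger-happy" false-positive response — and with
      probability ``fn_lapse_rate`` a healthy point (true TD above -6 dB)
      drops by 8-20 dB, an inattention false negative.

    The lapses are what make an unreliable exam recognizable: they push the
    measured field off the manifold of plausible fields and shift its mean
    in a signed, correctable way.  Setting ``exam_scale_sd = 0`` and both
    lapse rates to 0 recovers plain per-point Gaussian noise.
    """

    sd_floor: float = 1.0
    sd_slope: float = 0.15
    sd_cap: float = 6.0
    exam_scale_sd: float = 0.5
    exam_shift_sd: float = 1.5
    fp_lapse_rate: float = 0.08
    fn_lapse_rate: float = 0.04

    _FP_ELIGIBLE_BELOW = -10.0  # dB: only damaged points produce FP lapses
    _FN_ELIGIBLE_ABOVE = -6.0  # dB: only near-healthy points produce FN lapses

    def __post_init__(self) -> None:
        if self.sd_floor < 0 or self.sd_slope < 0 or self.sd_cap < self.sd_floor:
            raise ValueError("require sd_floor >= 0, sd_slope >= 0, sd_cap >= sd_floor")
        if self.exam_scale_sd < 0 or self.exam_shift_sd < 0 or not (
            0 <= self.fp_lapse_rate <= 0.5 and 0 <= self.fn_lapse_rate <= 0.5
        ):
            raise ValueError(
                "require exam_scale_sd >= 0, exam_shift_sd >= 0 and lapse rates in [0, 0.5]"
            )

    def sd(self, td_true: np.ndarray) -> np.ndarray:
        """Gaussian-component SD at a true damage level (exam factor 1)."""
        td_true = np.asarray(td_true, dtype=float)
        return np.minimum(self.sd_cap, self.sd_floor + self.sd_slope * np.maximum(0.0, -td_true))

    def sample_errors(self, td_true: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw one exam's additive errors for a (52,) true field."""
        scale = float(np.exp(rng.normal(0.0, self.exam_scale_sd))) if self.exam_scale_sd > 0 else 1.0
        err = rng.normal(0.0, 1.0, td_true.shape) * self.sd(td_true) * scale
        if self.exam_shift_sd > 0:
            err = err + rng.normal(0.0, self.exam_shift_sd * scale)
        if self.fp_lapse_rate > 0:
            fp = (rng.random(td_true.shape) < min(0.5, self.fp_lapse_rate * scale)) & (
                td_true <= self._FP_ELIGIBLE_BELOW
            )
            # the point reads near-normal regardless of its true depth
            err = np.where(fp, rng.uniform(-5.0, 3.0, td_true.shape) - td_true, err)
        if self.fn_lapse_rate > 0:
            fn = (rng.random(td_true.shape) < min(0.5, self.fn_lapse_rate * scale)) & (
                td_true >= self._FN_ELIGIBLE_ABOVE
            )
            err = np.where(fn, -rng.uniform(8.0, 20.0, td_true.shape), err)
        return err


@dataclass
class DefectArchetype:
    """A named spatial damage pattern: 52 nonnegative loadings summing to 1."""

    name: str
    weight_map: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weight_map, dtype=float)
        if w.shape != (N_POINTS,) or np.any(w < 0):
            raise ValueError("weight_map must be 52 nonnegative loadings")
        self.weight_map = w / w.sum()


def _arcuate_map(superior: bool) -> np.ndarray:
    # Bjerrum-area bundle: annulus 10-20 deg from fixation in one hemifield
    r = np.hypot(X_DEG, Y_DEG)
    hemi = Y_DEG > 0 if superior else Y_DEG < 0
    w = np.exp(-(((r - 15.0) / 5.0) ** 2)) * hemi
    return w + 1e-6


def _nasal_step_map() -> np.ndarray:
    # nasal field (positive x here), hugging the horizontal midline
    w = np.exp(-(np.abs(Y_DEG) / 7.0)) * (X_DEG >= 9)
    return w + 1e-6


def default_archetypes() -> list[DefectArchetype]:
    """The spatially structured defect patterns used by the generator.

    All default patterns are focal (nerve-fiber-bundle shaped): glaucomatous
    loss follows retinal nerve fiber anatomy, and keeping the true-field
    manifold structured is what lets a denoiser tell a genuine defect from a
    diffuse exam-level fluctuation.  A uniform pattern is available
    separately (:func:`diffuse_archetype`) for users modelling media opacity.
    """
    return [
        DefectArchetype("superior-arcuate", _arcuate_map(True)),
        DefectArchetype("inferior-arcuate", _arcuate_map(False)),
        DefectArchetype("nasal-step", _nasal_step_map()),
    ]


def diffuse_archetype() -> DefectArchetype:
    """Uniform loss across all 52 points (cataract-like, not shipped as a
    default because diffuse depression is how unreliable exams look)."""
    return DefectArchetype("diffuse", np.full(N_POINTS, 1.0 / N_POINTS))


_HEALTHY_JITTER_SD = 1.0  # dB, inter-point variation of an undamaged field
_SLOPE_FLOOR = 0.02  # diffuse share of progression not tied to the defect


def _mixture_map(archetypes: list[DefectArchetype], mixture: np.ndarray) -> np.ndarray:
    w = sum(m * a.weight_map for m, a in zip(mixture, archetypes))
    return w / w.sum()


def _true_eye_fields(
    config: CohortConfig,
    archetypes: list[DefectArchetype],
    mixture: np.ndarray | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Noise-free (n_exams, 52) trajectory plus exam times, baseline and slope."""
    if mixture is None:
        mixture = rng.dirichlet(np.full(len(archetypes), 0.8))
    wmap = _mixture_map(archetypes, mixture)
    target = rng.normal(config.baseline_mtd_mean, config.baseline_mtd_sd)
    target = float(np.clip(target, TD_MIN + 1.0, TD_MAX - 1.0))
    slope = rng.normal(config.slope_mean, config.slope_sd)
    jitter = rng.normal(0.0, _HEALTHY_JITTER_SD, N_POINTS)
    jitter -= jitter.mean()

    # per-point progression, concentrated on the defect but never purely focal
    v = (wmap + _SLOPE_FLOOR) / (1.0 + N_POINTS * _SLOPE_FLOOR)
    point_slopes = slope * N_POINTS * v

    intervals = config.interval_years * rng.uniform(0.8, 1.2, config.n_exams - 1)
    t = np.concatenate([[0.0], np.cumsum(intervals)])

    depth = target * N_POINTS * wmap if target < 0 else np.full(N_POINTS, target)
    base = jitter + depth

    fields = np.empty((config.n_exams, N_POINTS))
    for i, ti in enumerate(t):
        td = base + point_slopes * ti
        # the eye-level trajectory saturates at the instrument range
        goal = float(np.clip(target + slope * ti, TD_MIN + 1.0, TD_MAX - 1.0))
        # clamp to the measurable range, then restore the eye-level mean so the
        # mean-deviation trajectory stays linear despite floor saturation
        for _ in range(4):
            td = np.clip(td, TD_MIN, TD_MAX)
            err = goal - td.mean()
            if abs(err) < 1e-9:
                break
            td = td + err
        td = np.clip(td, TD_MIN, TD_MAX)
        if abs(goal - td.mean()) > 0.5:
            warnings.warn(
                f"baseline/progression target {goal:.1f} dB unreachable after "
                "clamping; best-effort field generated",
                stacklevel=2,
            )
        fields[i] = td
    return fields, t, target, slope


def generate_true_series(
    config: CohortConfig,
    archetype_mixture: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    eye_id: str = "eye",
    archetypes: list[DefectArchetype] | None = None,
) -> VFSeries:
    """One noise-free eye: structured baseline defect, linear progression."""
    rng = rng if rng is not None else np.random.default_rng([config.seed, _STREAM_STRUCTURE])
    archetypes = archetypes or default_archetypes()
    fields, t, _, _ = _true_eye_fields(config, archetypes, archetype_mixture, rng)
    exams = [VisualField(td=fields[i], t=t[i]) for i in range(config.n_exams)]
    return VFSeries(eye_id, exams)


def _draw_reliability(rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for key in ("fl", "fp", "fn"):
        mu, sd = RELIABILITY_MEANS[key], RELIABILITY_SDS[key]
        a, b = (0.0 - mu) / sd, (100.0 - mu) / sd
        out[key] = float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
    return out


def add_measurement_noise(
    series_true: VFSeries,
    noise_model: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    reliability_rng: np.random.Generator | None = None,
) -> VFSeries:
    """Overlay independent per-point Gaussian noise and reliability indices.

    Noise SD follows the damage-dependent model; measured values are clamped
    to the instrument range.  FL/FP/FN are drawn from truncated normals.
    """
    noise_model = noise_model or NoiseModel()
    rng = rng if rng is not None else np.random.default_rng(_STREAM_NOISE)
    reliability_rng = reliability_rng if reliability_rng is not None else rng
    exams = []
    for exam in series_true.exams:
        td = np.clip(exam.td + noise_model.sample_errors(exam.td, rng), TD_MIN, TD_MAX)
        rel = _draw_reliability(reliability_rng)
        exams.append(VisualField(td=td, t=exam.t, **rel))
    return VFSeries(series_true.eye_id, exams)


def generate_cohort(
    config: CohortConfig,
    noise_model: NoiseModel | None = None,
    archetypes: list[DefectArchetype] | None = None,
) -> tuple[list[VFSeries], list[VFSeries]]:
    """Full cohort of ``config.n_eyes`` eyes.

    Returns ``(true_cohort, noisy_cohort)``: the noise-free trajectories and
    their measured (noisy, reliability-annotated) counterparts, aligned
    eye-for-eye and exam-for-exam.
    """
    noise_model = noise_model or NoiseModel()
    archetypes = archetypes or default_archetypes()
    true_cohort, noisy_cohort = [], []
    for i in range(config.n_eyes):
        eye_id = f"eye{i:05d}"
        rng_s = np.random.default_rng([config.seed, _STREAM_STRUCTURE, i])
        rng_n = np.random.default_rng([config.seed, _STREAM_NOISE, i])
        rng_r = np.random.default_rng([config.seed, _STREAM_RELIABILITY, i])
        truth = generate_true_series(config, rng=rng_s, eye_id=eye_id, archetypes=archetypes)
        noisy = add_measurement_noise(truth, noise_model, rng=rng_n, reliability_rng=rng_r)
        true_cohort.append(truth)
        noisy_cohort.append(noisy)
    return true_cohort, noisy_cohort


def generate_test_retest(
    config: CohortConfig,
    noise_model: NoiseModel | None = None,
    n_pairs: int = 104,
    seed: int | None = None,
) -> list[tuple[VisualField, VisualField]]:
    """Test-retest pairs: two noisy measurements of one unchanged true field.

    Emulates a short-interval retest study — no progression between the two
    exams, independent noise realizations.
    """
    noise_model = noise_model or NoiseModel()
    seed = config.seed if seed is None else seed
    archetypes = default_archetypes()
    pairs = []
    for i in range(n_pairs):
        rng_s = np.random.default_rng([seed, _STREAM_STRUCTURE, 1_000_000 + i])
        rng_n = np.random.default_rng([seed, _STREAM_NOISE, 1_000_000 + i])
        rng_r = np.random.default_rng([seed, _STREAM_RELIABILITY, 1_000_000 + i])
        one = CohortConfig(
            n_eyes=1,
            n_exams=2,
            interval_years=config.interval_years,
            baseline_mtd_mean=config.baseline_mtd_mean,
            baseline_mtd_sd=config.baseline_mtd_sd,
            slope_mean=0.0,
            slope_sd=0.0,
            seed=seed,
        )
        truth = generate_true_series(one, rng=rng_s, eye_id=f"pair{i:05d}", archetypes=archetypes)
        td_true = truth.exams[0].td
        fields = []
        for _ in range(2):
            td = np.clip(td_true + noise_model.sample_errors(td_true, rng_n), TD_MIN, TD_MAX)
            rel = _draw_reliability(rng_r)
            fields.append(VisualField(td=td, t=0.0, **rel))
        pairs.append((fields[0], fields[1]))
    return pairs
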
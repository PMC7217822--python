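"""End-to-end synthetic experiments.

Two studies are orchestrated from a single config:

1. *Test-retest*: train the VAE on an independent synthetic cohort, then on
   pairs of same-day measurements regress the retest-minus-test mTD
   difference on the reconstruction-minus-test difference.  A positive,
   significant slope means the reconstruction anticipates where the retest
   will land — the reconstruction error is measuring noise, not signal.
2. *Trend*: on a 10-exam cohort, run unweighted and reconstruction-weighted
   mTD trend analysis and binomial PLR over truncated series (VF1-3 ...
   VF1-9), and evaluate consistency against the full series, final-exam
   prediction error, and Kaplan-Meier time to first detection.

The VAE is always trained on a cohort disjoint from the evaluation cohort
(separate generator substreams), mirroring a train-hospital / test-hospital
split.  Everything is deterministic under the experiment seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from . import evaluation as ev
from . import trend as tr
from . import vae as vq
from .synthetic import CohortConfig, NoiseModel, generate_cohort, generate_test_retest
from .vae import VAEConfig, VAEParameters
from .vf_core import VFSeries, compute_mtd

logger = logging.getLogger("vfprog")

REPORT_SCHEMA_VERSION = 1


@dataclass
class ExperimentConfig:
    """Resolved settings of one synthetic experiment."""

    seed: int = 0
    n_train_eyes: int = 200  # 200 eyes x 10 exams = 2000 training fields
    n_eval_eyes: int = 500
    n_pairs: int = 104
    cohort: CohortConfig = dc_field(default_factory=CohortConfig)
    noise: NoiseModel = dc_field(default_factory=NoiseModel)
    vae: VAEConfig = dc_field(default_factory=VAEConfig)
    #: floor (dB) on |measured - reconstructed| in the weight denominator.
    #: Set at the mTD measurement noise floor: an exam whose reconstruction
    #: agrees to better than ~0.25 dB is not thereby more reliable than one
    #: agreeing to 0.25 dB, and a far smaller floor lets a single
    #: chance-perfect exam dominate the weighted fit.
    epsilon: float = 0.25
    truncations: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9)
    trend_alpha: float = tr.TREND_ALPHA

    def train_cohort_config(self) -> CohortConfig:
        return dataclasses.replace(
            self.cohort, n_eyes=self.n_train_eyes, seed=self.seed * 3 + 1
        )

    def eval_cohort_config(self) -> CohortConfig:
        return dataclasses.replace(
            self.cohort, n_eyes=self.n_eval_eyes, seed=self.seed * 3 + 2
        )

    def vae_config(self) -> VAEConfig:
        return dataclasses.replace(self.vae, seed=self.seed * 3 + 3)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig(**d["cohort"])
        if "noise" in d:
            d["noise"] = NoiseModel(**d["noise"])
        if "vae" in d:
            vd = dict(d["vae"])
            if "hidden_dims" in vd:
                vd["hidden_dims"] = tuple(vd["hidden_dims"])
            d["vae"] = VAEConfig(**vd)
        if "truncations" in d:
            d["truncations"] = tuple(d["truncations"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)


def train_experiment_vae(config: ExperimentConfig) -> VAEParameters:
    """Train the denoiser on the experiment's independent training cohort."""
    t0 = time.time()
    _, noisy = generate_cohort(config.train_cohort_config(), config.noise)
    fields = vq.fields_from_cohort(noisy)
    logger.info("training VAE on %d fields", len(fields))
    params = vq.train_vae(fields, config.vae_config())
    logger.info(
        "VAE trained in %.1fs, final loss %.5f",
        time.time() - t0,
        params.history[-1]["loss"],
    )
    return params


def run_test_retest(
    config: ExperimentConfig, params: VAEParameters | None = None
) -> dict:
    """Test-retest experiment: does reconstruction error predict the retest?

    Regresses (mTD_retest − mTD_test) on (mTD_VAE − mTD_test) across pairs.
    Returns slope, two-sided p and Pearson correlation; with degenerate
    (zero-variance) differences the correlation is reported as missing.
    """
    params = params if params is not None else train_experiment_vae(config)
    pairs = generate_test_retest(config.cohort, config.noise, config.n_pairs, seed=config.seed * 3 + 2)
    mtd_test = np.array([compute_mtd(a) for a, _ in pairs])
    mtd_retest = np.array([compute_mtd(b) for _, b in pairs])
    recon = vq.reconstruct_matrix(np.stack([a.td for a, _ in pairs]), params)
    mtd_vae = recon.mean(axis=1)
    x = mtd_vae - mtd_test
    y = mtd_retest - mtd_test
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "experiment": "test_retest",
        "config_hash": config.config_hash(),
        "n_pairs": len(pairs),
        "mtd_test_mean": float(mtd_test.mean()),
        "mtd_test_sd": float(mtd_test.std(ddof=1)),
        "retest_mtd_correlation": float(np.corrcoef(mtd_test, mtd_retest)[0, 1]),
    }
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        report.update(slope=None, slope_p=None, correlation=None)
        return report
    fit = tr.ols_fit(x, y)
    report.update(
        slope=fit.slope,
        slope_p=fit.slope_p,
        correlation=float(np.corrcoef(x, y)[0, 1]),
    )
    return report


def _method_calls_and_predictions(
    cohort: list[VFSeries],
    recons: list[VFSeries] | None,
    scheme: tr.WeightScheme,
    truncations: tuple[int, ...],
    alpha: float,
    want_plr: bool,
):
    """Per-eye significance calls and final-exam predictions for one scheme."""
    n_eyes = len(cohort)
    full_len = len(cohort[0])
    mtd_full = np.zeros(n_eyes, dtype=bool)
    plr_full = np.zeros(n_eyes, dtype=bool)
    mtd_trunc = {k: np.zeros(n_eyes, dtype=bool) for k in truncations}
    plr_trunc = {k: np.zeros(n_eyes, dtype=bool) for k in truncations}
    preds = {k: np.zeros(n_eyes) for k in truncations}
    for i, series in enumerate(cohort):
        recon = recons[i] if recons is not None else None
        t_final = series.times[-1]
        for k in (*truncations, full_len):
            sub = series.truncate(k)
            sub_recon = recon.truncate(k) if recon is not None else None
            fit = tr.mtd_trend(sub, scheme, sub_recon)
            sig = tr.trend_is_significant(fit, alpha)
            if want_plr:
                plr_sig = tr.binomial_plr_series(sub, scheme, sub_recon).significant
            if k == full_len:
                mtd_full[i] = sig
                if want_plr:
                    plr_full[i] = plr_sig
            else:
                mtd_trunc[k][i] = sig
                preds[k][i] = fit.predict(t_final)
                if want_plr:
                    plr_trunc[k][i] = plr_sig
    out = {
        "mtd_calls": ev.ProgressionCalls(mtd_full, mtd_trunc),
        "predictions": preds,
    }
    if want_plr:
        out["plr_calls"] = ev.ProgressionCalls(plr_full, plr_trunc)
    return out


def run_trend_experiment(
    config: ExperimentConfig, params: VAEParameters | None = None
) -> dict:
    """Trend experiment: weighted vs unweighted progression analysis.

    Returns a report with, per method: PBP/PBNP/PIP per truncation, mean
    squared final-exam prediction errors, paired Wilcoxon comparisons of
    the error curves, denoising summary, and logrank comparisons of
    detection times.
    """
    params = params if params is not None else train_experiment_vae(config)
    truth, noisy = generate_cohort(config.eval_cohort_config(), config.noise)
    recons = [
        VFSeries(
            s.eye_id,
            [
                dataclasses.replace(e, td=td)
                for e, td in zip(s.exams, vq.reconstruct_matrix(s.td_matrix, params))
            ],
        )
        for s in noisy
    ]

    mse_measured = float(
        np.mean([(n.td_matrix - t.td_matrix) ** 2 for n, t in zip(noisy, truth)])
    )
    mse_recon = float(
        np.mean([(r.td_matrix - t.td_matrix) ** 2 for r, t in zip(recons, truth)])
    )

    unw = tr.WeightScheme("unweighted", config.epsilon)
    w_mtd = tr.WeightScheme("vae_mtd", config.epsilon)
    w_pt = tr.WeightScheme("vae_pointwise", config.epsilon)

    logger.info("running trend analyses on %d eyes", len(noisy))
    res_unw = _method_calls_and_predictions(
        noisy, None, unw, config.truncations, config.trend_alpha, want_plr=True
    )
    res_wm = _method_calls_and_predictions(
        noisy, recons, w_mtd, config.truncations, config.trend_alpha, want_plr=False
    )
    res_wp = _method_calls_and_predictions(
        noisy, recons, w_pt, config.truncations, config.trend_alpha, want_plr=True
    )

    observed = np.array([s.mtd[-1] for s in noisy])
    err_unw = ev.prediction_errors(observed, res_unw["predictions"])
    err_w = ev.prediction_errors(observed, res_wm["predictions"])
    ks = sorted(err_unw)
    err_curve_unw = [err_unw[k] for k in ks]
    err_curve_w = [err_w[k] for k in ks]

    cons = {
        "mtd_unweighted": ev.consistency(res_unw["mtd_calls"]),
        "mtd_weighted": ev.consistency(res_wm["mtd_calls"]),
        "plr_unweighted": ev.consistency(res_unw["plr_calls"]),
        "plr_weighted": ev.consistency(res_wp["plr_calls"]),
    }

    surv_unw = ev.detection_survival(res_unw["plr_calls"])
    surv_w = ev.detection_survival(res_wp["plr_calls"])
    lr_stat, lr_p = ev.logrank(surv_unw, surv_w)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "experiment": "trend",
        "config_hash": config.config_hash(),
        "n_eyes": len(noisy),
        "truncations": list(ks),
        "denoising": {
            "mse_measured_vs_truth": mse_measured,
            "mse_recon_vs_truth": mse_recon,
        },
        "prediction_mse": {
            "unweighted": err_curve_unw,
            "weighted": err_curve_w,
            "wilcoxon_p": (
                ev.paired_wilcoxon(err_curve_unw, err_curve_w) if len(ks) >= 5 else None
            ),
        },
        "consistency": {
            name: df.reset_index().to_dict(orient="list") for name, df in cons.items()
        },
        "consistency_wilcoxon_p": {
            f"mtd_{m}": (
                ev.paired_wilcoxon(
                    cons["mtd_unweighted"][m].to_numpy(),
                    cons["mtd_weighted"][m].to_numpy(),
                )
                if len(ks) >= 5
                else None
            )
            for m in ("pbp", "pbnp", "pip")
        },
        "detection": {
            "plr_unweighted_mean_exams": float(np.mean([r.time for r in surv_unw])),
            "plr_weighted_mean_exams": float(np.mean([r.time for r in surv_w])),
            "plr_unweighted_detected": int(sum(r.event for r in surv_unw)),
            "plr_weighted_detected": int(sum(r.event for r in surv_w)),
            "logrank_statistic": lr_stat,
            "logrank_p": lr_p,
        },
    }
    return report
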
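"""Reference evaluation protocols on synthetic cohorts.

These functions bundle the study-style experiments the package is validated
with — desk-scale analogues of a multicentre validation: subject-wise
cross-validated stager training on a separable cohort, a label-permutation
chance control, self-supervised time-reversal discrimination, the
warm-vs-cold-start comparison and ICC recovery.  They are used by the test
suite and the reproduction script so both report the same computations.

Problem sizes are deliberately small (tens of subjects, ~2.5 h in bed per
night, tiny network preset): large enough for the qualitative behaviour —
sleep/wake strongly separable, REM vs NREM weakly — to emerge, small enough
to run on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np

from . import synthetic
from .agreement import evaluate_labels
from .core import Hypnogram
from .pipeline import _collapse_labels
from .preprocess import epochize
from .sleepnet import (
    SleepNet,
    SSLTaskConfig,
    fit_sleepnet,
    pretrain_ssl,
    tiny_config,
    train_sleepnet,
)


def make_stager_cohort(
    seed: int,
    n_subjects: int = 20,
    n_nights: int = 2,
    tib_hours: float = 2.5,
):
    """In-memory labelled cohort: (EpochTensor, Hypnogram, subject_id) nights."""
    stage_model = synthetic.default_stage_model(
        time_in_bed_mean_hours=tib_hours, time_in_bed_sd_minutes=10.0
    )
    movement = synthetic.default_movement_model()
    nights = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        for night in range(n_nights):
            n_epochs = max(
                60,
                int(
                    round(
                        np.random.default_rng(
                            synthetic._sub_seed(seed, sid, night, "len")
                        ).normal(tib_hours * 120, 20)
                    )
                ),
            )
            hyp = synthetic.simulate_hypnogram(
                stage_model,
                n_epochs,
                synthetic._sub_seed(seed, sid, night, "hyp"),
                start_time=f"2024-03-{4 + night:02d}T23:00:00",
            )
            rec = synthetic.simulate_recording(
                hyp, movement, seed=synthetic._sub_seed(seed, sid, night, "sig"), subject_id=sid
            )
            nights.append((epochize(rec), hyp, sid))
    return nights


def stager_cv_experiment(
    seed: int,
    nights=None,
    k: int = 5,
    max_epochs: int = 2,
    pretrained_state=None,
) -> dict:
    """Subject-wise CV of the tiny stager; pooled out-of-fold agreement.

    Returns kappa and balanced accuracy under the five-, three- and
    two-class schemes plus the raw CV result.
    """
    nights = nights if nights is not None else make_stager_cohort(seed)
    cfg = tiny_config(seed=seed, max_epochs=max_epochs)
    cv = train_sleepnet(nights, cfg, k=k, seed=seed, pretrained_state=pretrained_state)
    pooled_true = np.concatenate([cv.truths[s] for s in sorted(cv.truths)])
    pooled_pred = np.concatenate(
        [cv.predictions[s].labels for s in sorted(cv.truths)]
    )
    out = {"cv": cv}
    for scheme in ("five_class", "three_class", "two_class"):
        rep = evaluate_labels(
            _collapse_labels(pooled_true, scheme),
            _collapse_labels(pooled_pred, scheme),
            scheme,
        )
        out[f"kappa_{scheme}"] = rep.kappa
        out[f"balanced_accuracy_{scheme}"] = rep.balanced_accuracy
    return out


def shuffled_label_experiment(seed: int, nights=None, k: int = 5) -> float:
    """Chance control: permute epoch labels across the cohort, re-run CV.

    Returns the pooled out-of-fold five-class kappa (expected ~0).
    """
    nights = nights if nights is not None else make_stager_cohort(seed)
    rng = np.random.default_rng(seed + 17)
    all_labels = np.concatenate([h.labels for _, h, _ in nights])
    perm = rng.permutation(len(all_labels))
    shuffled = all_labels[perm]
    out_nights = []
    pos = 0
    for tensor, hyp, sid in nights:
        n = len(hyp)
        out_nights.append(
            (tensor, Hypnogram(hyp.epoch_start_times, shuffled[pos : pos + n]), sid)
        )
        pos += n
    cfg = tiny_config(seed=seed, max_epochs=1)
    cv = train_sleepnet(out_nights, cfg, k=k, seed=seed)
    pooled_true = np.concatenate([cv.truths[s] for s in sorted(cv.truths)])
    pooled_pred = np.concatenate([cv.predictions[s].labels for s in sorted(cv.truths)])
    return evaluate_labels(pooled_true, pooled_pred, "five_class").kappa


def unlabeled_cohort_windows(seed: int, n_windows: int = 1200) -> np.ndarray:
    """Unlabelled stage-mix windows from the standard generator.

    Emulates a free-living pretraining corpus: the same signal model as the
    labelled cohort, with extra wake mixed in so movement of all scales
    appears.
    """
    stage_model = synthetic.default_stage_model(time_in_bed_mean_hours=2.0)
    movement = synthetic.default_movement_model()
    hyp = synthetic.simulate_hypnogram(stage_model, n_windows, seed, start_time="2024-01-01T00:00:00")
    rng = np.random.default_rng(seed + 1)
    labels = hyp.labels.copy()
    labels[rng.random(n_windows) < 0.4] = "W"
    rec = synthetic.simulate_recording(
        Hypnogram(hyp.epoch_start_times, labels), movement, seed=seed + 2
    )
    return epochize(rec).epochs.astype(float)


def asymmetric_burst_windows(seed: int, n_windows: int = 1200) -> np.ndarray:
    """Purpose-built windows dominated by time-asymmetric movement bursts.

    Frequent high-amplitude bursts (abrupt attack, gradual decay) over a
    quiet baseline: the time direction is detectable by construction, which
    is what the time-reversal discrimination check requires.
    """
    movement = synthetic.MovementModel(
        baseline_noise_sd_mg={s: 5.0 for s in synthetic.STAGES},
        burst_rate_per_min={s: 10.0 for s in synthetic.STAGES},
        burst_amplitude_sd_mg={s: 150.0 for s in synthetic.STAGES},
        burst_attack_fraction=0.1,
        device_noise_sd_mg=2.0,
    )
    stage_model = synthetic.default_stage_model()
    hyp = synthetic.simulate_hypnogram(
        stage_model, n_windows, seed, start_time="2024-01-01T00:00:00"
    )
    labels = np.array(["W"] * n_windows, dtype=object)
    rec = synthetic.simulate_recording(
        Hypnogram(hyp.epoch_start_times, labels), movement, seed=seed + 1
    )
    return epochize(rec).epochs.astype(float)


def ssl_reversal_experiment(seed: int, n_windows: int = 1200, epochs: int = 4) -> dict:
    """Time-reversal discrimination on asymmetric bursts; held-out AUC."""
    X = asymmetric_burst_windows(seed, n_windows)
    cfg = tiny_config(seed=seed)
    model = SleepNet(cfg)
    res = pretrain_ssl(
        model,
        X,
        SSLTaskConfig(tasks=("time_reversal",), seed=seed),
        epochs=epochs,
    )
    return {
        "auc": res.task_auc["time_reversal"],
        "initial_loss": res.initial_loss,
        "final_loss": res.final_loss,
        "state": res.extractor_state,
    }


def make_morphology_cohort(seed: int, n_subjects: int = 6, n_epochs: int = 180):
    """Single-night cohort under the burst-morphology movement preset.

    Stages share a baseline variance and differ in burst rate, amplitude
    and shape, so per-epoch variance alone is a weak cue; used to assess
    the value of pretrained movement-shape features.
    """
    stage_model = synthetic.default_stage_model(
        time_in_bed_mean_hours=1.5, time_in_bed_sd_minutes=10.0
    )
    movement = synthetic.burst_morphology_movement_model()
    nights = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        hyp = synthetic.simulate_hypnogram(
            stage_model,
            n_epochs,
            synthetic._sub_seed(seed, sid, "hyp"),
            start_time="2024-03-04T23:00:00",
        )
        rec = synthetic.simulate_recording(
            hyp, movement, seed=synthetic._sub_seed(seed, sid, "sig"), subject_id=sid
        )
        nights.append((epochize(rec), hyp, sid))
    return nights


def warm_cold_experiment(seeds=(0, 1, 2), n_subjects: int = 6, max_epochs: int = 3) -> list:
    """Paired warm- vs cold-start training losses at an equal small budget.

    For each seed: pretrain the extractor by time-reversal discrimination
    on burst-dominated unlabelled windows (where the task is learnable by
    construction), then fine-tune on a small morphology-separable labelled
    cohort, against a cold start with identical initialisation, batch order
    and budget.  Returns a list of (warm_final_loss, cold_final_loss).
    """
    out = []
    for seed in seeds:
        nights = make_morphology_cohort(seed, n_subjects=n_subjects)
        X = asymmetric_burst_windows(seed + 1000, n_windows=1500)
        cfg = tiny_config(seed=seed, max_epochs=max_epochs)
        warm = SleepNet(cfg)
        pretrain_ssl(
            warm, X, SSLTaskConfig(tasks=("time_reversal",), seed=seed), epochs=5
        )
        warm_losses = fit_sleepnet(warm, nights, cfg, rng=np.random.default_rng(seed + 5))
        cold = SleepNet(cfg)
        cold_losses = fit_sleepnet(cold, nights, cfg, rng=np.random.default_rng(seed + 5))
        out.append((warm_losses[-1], cold_losses[-1]))
    return out
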
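"""Agreement battery: confusion, kappa/F1/balanced accuracy, Bland-Altman,
fold assignment and stratified reports."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import balanced_accuracy_score, cohen_kappa_score, f1_score

from sleepstagekit.agreement import (
    ConfusionMatrix,
    agreement_metrics,
    bland_altman,
    confusion,
    evaluate_labels,
    make_folds,
    stratified_report,
    subject_level_report,
)


class TestConfusion:
    def test_identical_sequences_diagonal(self):
        cm = confusion(["W", "R", "NREM"], ["W", "R", "NREM"], "three_class")
        assert np.trace(cm.counts) == 3 and cm.counts.sum() == 3

    def test_direct_count(self):
        cm = confusion(["W", "W", "R", "NREM"], ["W", "R", "R", "NREM"], "three_class")
        labels = list(cm.labels)
        assert cm.counts[labels.index("W"), labels.index("R")] == 1
        assert cm.total == 4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["W"], ["W", "R"], "three_class")

    def test_alien_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["W", "Q"], ["W", "W"], "three_class")


class TestAgreementMetrics:
    def test_worked_2x2_example(self):
        """[[40,10],[5,45]]: p_o=0.85, p_e=0.5, kappa=0.70, BA=0.85."""
        cm = ConfusionMatrix(np.array([[40, 10], [5, 45]]), ("A", "B"))
        rep = agreement_metrics(cm)
        assert rep.kappa == pytest.approx(0.70)
        assert rep.balanced_accuracy == pytest.approx((0.80 + 0.90) / 2)
        f1a = 2 * 40 / (2 * 40 + 5 + 10)
        f1b = 2 * 45 / (2 * 45 + 10 + 5)
        assert rep.macro_f1 == pytest.approx((f1a + f1b) / 2)
        assert rep.macro_f1 == pytest.approx(0.8496, abs=5e-4)

    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(np.diag([10, 20, 30]), ("a", "b", "c"))
        rep = agreement_metrics(cm)
        assert rep.kappa == pytest.approx(1.0)
        assert rep.macro_f1 == pytest.approx(1.0)
        assert rep.balanced_accuracy == pytest.approx(1.0)

    def test_constant_prediction_chance_kappa(self):
        cm = ConfusionMatrix(np.array([[50, 0], [50, 0]]), ("A", "B"))
        assert agreement_metrics(cm).kappa == pytest.approx(0.0)

    def test_degenerate_marginals_flagged(self):
        cm = ConfusionMatrix(np.array([[7, 0], [0, 0]]), ("A", "B"))
        rep = agreement_metrics(cm)
        assert not rep.kappa_defined and np.isnan(rep.kappa)

    def test_matches_bruteforce_formulas_on_random_matrices(self):
        """Direct formula evaluation on 200 random confusion matrices (1e-12)."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            counts = rng.integers(0, 50, size=(k, k))
            counts[np.arange(k), np.arange(k)] += 1  # avoid degenerate marginals
            cm = ConfusionMatrix(counts, tuple(f"c{i}" for i in range(k)))
            rep = agreement_metrics(cm)
            # independent brute force: explicit loops
            n = counts.sum()
            po = sum(counts[i, i] for i in range(k)) / n
            pe = sum(counts[i, :].sum() * counts[:, i].sum() for i in range(k)) / n**2
            kappa = (po - pe) / (1 - pe)
            sens, spec, f1s = [], [], []
            for i in range(k):
                tp = counts[i, i]
                fn = counts[i, :].sum() - tp
                fp = counts[:, i].sum() - tp
                tn = n - tp - fn - fp
                sens.append(tp / (tp + fn) if tp + fn else np.nan)
                spec.append(tn / (tn + fp) if tn + fp else np.nan)
                f1s.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else np.nan)
            assert rep.kappa == pytest.approx(kappa, abs=1e-12)
            assert rep.balanced_accuracy == pytest.approx(np.nanmean(sens), abs=1e-12)
            assert rep.macro_f1 == pytest.approx(np.nanmean(f1s), abs=1e-12)
            for i in range(k):
                got_s = rep.per_class["sensitivity"].iloc[i]
                got_p = rep.per_class["specificity"].iloc[i]
                if not np.isnan(sens[i]):
                    assert got_s == pytest.approx(sens[i], abs=1e-12)
                assert got_p == pytest.approx(spec[i], abs=1e-12)

    def test_matches_sklearn_on_label_sequences(self):
        rng = np.random.default_rng(1)
        classes = np.array(["W", "NREM", "R"], dtype=object)
        for _ in range(50):
            n = int(rng.integers(30, 200))
            true = np.concatenate([classes, classes[rng.integers(0, 3, n)]])
            pred = classes[rng.integers(0, 3, len(true))]
            rep = evaluate_labels(true, pred, "three_class")
            order = list(rep.per_class.index)
            assert rep.kappa == pytest.approx(
                cohen_kappa_score(true.astype(str), pred.astype(str)), abs=1e-12)
            assert rep.macro_f1 == pytest.approx(
                f1_score(true.astype(str), pred.astype(str), labels=order,
                         average="macro", zero_division=0), abs=1e-12)
            assert rep.balanced_accuracy == pytest.approx(
                balanced_accuracy_score(true.astype(str), pred.astype(str)), abs=1e-12)

    def test_kappa_invariant_under_class_permutation(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 40, size=(4, 4))
        labels = ("a", "b", "c", "d")
        base = agreement_metrics(ConfusionMatrix(counts, labels)).kappa
        perm = rng.permutation(4)
        permuted = counts[np.ix_(perm, perm)]
        got = agreement_metrics(
            ConfusionMatrix(permuted, tuple(labels[i] for i in perm))).kappa
        assert got == pytest.approx(base, abs=1e-12)


class TestSubjectLevelReport:
    def test_single_perfect_subject(self):
        summary, per = subject_level_report(
            {"A": ["W", "R", "NREM"]}, {"A": ["W", "R", "NREM"]}, "three_class")
        assert summary.loc["subject_mean", "macro_f1"] == pytest.approx(1.0)
        assert summary.loc["subject_sd", "macro_f1"] == 0.0

    def test_mean_and_sample_sd_of_two_subjects(self):
        """Per-subject F1 {0.6, 0.8} -> 0.7 +- 0.1414 (sample sd)."""
        # subject A: W/SLEEP with macro F1 0.6; construct via direct counts
        # easier: verify the aggregation rule itself on a crafted per-subject frame
        truths = {"A": ["W", "W", "SLEEP", "SLEEP"], "B": ["W", "SLEEP", "W", "SLEEP"]}
        preds = {"A": ["W", "W", "SLEEP", "SLEEP"], "B": ["W", "SLEEP", "SLEEP", "SLEEP"]}
        summary, per = subject_level_report(truths, preds, "two_class")
        f1s = per["macro_f1"].to_numpy()
        assert summary.loc["subject_mean", "macro_f1"] == pytest.approx(f1s.mean())
        assert summary.loc["subject_sd", "macro_f1"] == pytest.approx(
            f1s.std(ddof=1))
        assert {"subject_mean", "subject_sd", "epoch_pooled"} <= set(summary.index)

    def test_single_class_subject_excluded_from_kappa(self):
        truths = {"A": ["SLEEP", "SLEEP"], "B": ["W", "SLEEP"]}
        preds = {"A": ["SLEEP", "SLEEP"], "B": ["W", "SLEEP"]}
        summary, per = subject_level_report(truths, preds, "two_class")
        assert np.isnan(per.loc["A", "kappa"])
        assert summary.loc["subject_mean", "kappa"] == pytest.approx(1.0)


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "tst")
        assert res.mean_bias == 0.0
        assert res.loa_low == 0.0 and res.loa_high == 0.0

    def test_closed_form_differences_4_and_6(self):
        """Differences {4, 6}: bias 5, sd sqrt(2), LoA (2.228, 7.772)."""
        res = bland_altman([0.0, 0.0], [4.0, 6.0], "tst")
        assert res.mean_bias == pytest.approx(5.0)
        assert res.sd_diff == pytest.approx(np.sqrt(2))
        assert res.loa_low == pytest.approx(5 - 1.96 * np.sqrt(2), abs=5e-4)
        assert res.loa_high == pytest.approx(7.772, abs=5e-4)

    def test_sign_convention_overestimation_positive(self):
        res = bland_altman([100.0, 100.0], [110.0, 120.0], "nrem")
        assert res.mean_bias > 0  # estimate above reference = overestimation

    def test_recovers_generating_gaussian(self):
        """Bias and sd of simulated differences within 2 standard errors."""
        rng = np.random.default_rng(3)
        n, mu, sd = 500, 12.0, 30.0
        ref = rng.normal(400, 50, n)
        est = ref + rng.normal(mu, sd, n)
        res = bland_altman(ref, est, "tst")
        assert abs(res.mean_bias - mu) < 2 * sd / np.sqrt(n)
        assert abs(res.sd_diff - sd) < 2 * sd / np.sqrt(2 * (n - 1))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0], "tst")


class TestMakeFolds:
    def test_balanced_partition(self):
        folds = make_folds([f"S{i}" for i in range(10)], k=5, seed=0)
        sizes = [len(folds.fold(i)) for i in range(5)]
        assert sizes == [2] * 5
        union = sorted(s for i in range(5) for s in folds.fold(i))
        assert union == sorted(f"S{i}" for i in range(10))

    def test_deterministic_under_seed(self):
        a = make_folds([f"S{i}" for i in range(13)], k=5, seed=9)
        b = make_folds([f"S{i}" for i in range(13)], k=5, seed=9)
        assert a.assignment == b.assignment

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["A", "B"], k=5, seed=0)


class TestStratifiedReport:
    def _per_subject(self):
        return pd.DataFrame(
            {"kappa": [0.8, 0.7, 0.3, 0.2], "macro_f1": [0.9, 0.8, 0.5, 0.4]},
            index=["A", "B", "C", "D"],
        )

    def test_single_stratum_equals_plain_mean(self):
        per = self._per_subject()
        out = stratified_report(per, {s: "all" for s in per.index}, min_n=1)
        assert out.loc["all", "kappa_mean"] == pytest.approx(per["kappa"].mean())
        assert out.loc["all", "n"] == 4

    def test_noisier_stratum_scores_lower(self):
        per = self._per_subject()
        strata = {"A": "clean", "B": "clean", "C": "noisy", "D": "noisy"}
        out = stratified_report(per, strata, min_n=1)
        assert out.loc["noisy", "kappa_mean"] < out.loc["clean", "kappa_mean"]
        assert out["n"].sum() == 4

    def test_unknown_subject_rejected(self):
        with pytest.raises(ValueError):
            stratified_report(self._per_subject(), {"A": "x"})

    def test_small_strata_flagged(self):
        per = self._per_subject()
        strata = {"A": "big", "B": "big", "C": "big", "D": "tiny"}
        out = stratified_report(per, strata, min_n=2)
        assert out.loc["tiny", "flagged_small"]
        assert not out.loc["big", "flagged_small"]


def test_figure_rendering_writes_files(tmp_path):
    pytest.importorskip("matplotlib")
    from sleepstagekit.agreement import bland_altman_plot, confusion_matrix_plot

    rng = np.random.default_rng(5)
    ref = rng.normal(400, 50, 30)
    est = ref + rng.normal(10, 20, 30)
    res = bland_altman_plot(ref, est, "total sleep (min)", tmp_path / "ba.svg")
    assert (tmp_path / "ba.svg").stat().st_size > 0
    assert res.n_nights == 30
    cm = ConfusionMatrix(np.array([[40, 10], [5, 45]]), ("W", "SLEEP"))
    confusion_matrix_plot(cm, tmp_path / "cm.svg")
    assert (tmp_path / "cm.svg").stat().st_size > 0
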
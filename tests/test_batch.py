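import numpy as np
import pandas as pd
import pytest

from metaboflow import (
    BatchDesign,
    correct_combat,
    correct_eigenms,
    correct_qcrlsc,
    evaluate_correction,
    gradient_length,
    select_best_correction,
    simulate_batched_table,
)


def centered_log_delta(corrected, clean):
    """Per-feature-centered log difference: the time/batch-varying error."""
    d = np.log(corrected.values) - np.log(clean.values)
    return d - d.mean(axis=1, keepdims=True)


class TestComBat:
    def test_single_batch_is_identity_with_warning(self):
        table, design, _ = simulate_batched_table(
            n_features=30, n_samples=12, batches=1, batch_shift=[1], seed=0
        )
        with pytest.warns(UserWarning, match="single batch"):
            out = correct_combat(table, design)
        np.testing.assert_array_equal(out.values, table.values)

    def test_removes_planted_multiplicative_shift(self):
        table, design, clean = simulate_batched_table(
            n_features=150, n_samples=40, batches=2, batch_shift=[1, 2], seed=3
        )
        out = correct_combat(table, design)
        b1 = [i for i, b in enumerate(design.batch) if b == "B1"]
        b2 = [i for i, b in enumerate(design.batch) if b == "B2"]
        log_ratio = np.log(out.values[:, b2].mean(1) / out.values[:, b1].mean(1))
        assert abs(log_ratio.mean()) < 0.1

    def test_near_noop_on_clean_data(self):
        _, design, clean = simulate_batched_table(
            n_features=150, n_samples=40, batches=2, batch_shift=[1, 1], seed=3
        )
        out = correct_combat(clean, design)
        rel = np.linalg.norm(np.log(out.values) - np.log(clean.values)) / np.linalg.norm(
            np.log(clean.values)
        )
        assert rel < 0.05

    def test_preserves_shape_and_positivity(self):
        table, design, _ = simulate_batched_table(
            n_features=60, n_samples=24, batches=2, seed=5
        )
        out = correct_combat(table, design)
        assert out.shape == table.shape
        assert (out.values > 0).all()


class TestEigenMS:
    def test_clean_residuals_leave_data_untouched(self):
        _, design, clean = simulate_batched_table(
            n_features=100, n_samples=40, batches=2, batch_shift=[1, 1], qc_every=0, seed=4
        )
        out = correct_eigenms(clean, design, seed=1)
        rel = np.linalg.norm(np.log(out.values) - np.log(clean.values))
        assert rel < 1e-9 or rel / np.linalg.norm(np.log(clean.values)) < 0.02

    def test_removes_planted_rank_one_drift(self):
        _, design, clean = simulate_batched_table(
            n_features=100, n_samples=40, batches=2, batch_shift=[1, 1], qc_every=0, seed=4
        )
        rng = np.random.default_rng(0)
        u = rng.normal(1.0, 0.3, 100)
        v = np.linspace(0, 1, 40)
        dirty = clean * np.exp(0.8 * np.outer(u, v))
        out = correct_eigenms(dirty, design, seed=1)
        before = np.var(centered_log_delta(dirty, clean))
        after = np.var(centered_log_delta(out, clean))
        assert 1 - after / before >= 0.8

    def test_group_differences_preserved(self):
        _, design, clean = simulate_batched_table(
            n_features=100, n_samples=48, batches=2, batch_shift=[1, 1], qc_every=6, seed=9
        )
        rng = np.random.default_rng(1)
        dirty = clean * np.exp(
            0.5 * np.outer(rng.normal(1, 0.3, 100), np.linspace(0, 1, 48))
        )
        out = correct_eigenms(dirty, design, seed=1)
        ga = [i for i, g in enumerate(design.group) if g == "A"]
        gb = [i for i, g in enumerate(design.group) if g == "B"]

        def diff(m):
            return np.log(m.values[:, ga].mean(1)) - np.log(m.values[:, gb].mean(1))

        top = np.argsort(-np.abs(diff(clean)))[:10]  # features with real effects
        rel_err = np.abs(diff(out)[top] - diff(clean)[top]) / np.abs(diff(clean)[top])
        assert np.median(rel_err) < 0.25


class TestQcRlsc:
    def test_needs_three_qcs(self):
        table, design, _ = simulate_batched_table(
            n_features=20, n_samples=20, batches=1, batch_shift=[1], qc_every=10, seed=0
        )
        assert design.n_qc == 2
        with pytest.raises(ValueError, match="3 QC"):
            correct_qcrlsc(table, design)

    def test_flat_qc_trace_is_near_identity(self):
        _, design, clean = simulate_batched_table(
            n_features=40, n_samples=40, batches=1, batch_shift=[1],
            qc_every=5, noise_sd=0.0, seed=1
        )
        out = correct_qcrlsc(clean, design)
        qc = np.array(design.is_qc)
        np.testing.assert_allclose(out.values[:, qc], clean.values[:, qc], rtol=1e-6)

    def test_linear_drift_halves_qc_cv(self):
        table, design, _ = simulate_batched_table(
            n_features=80, n_samples=60, batches=1, batch_shift=[1],
            qc_every=5, noise_sd=0.05, seed=5
        )
        order = np.array(design.injection_order)
        dirty = table * (1 + 0.01 * order)[None, :]
        out = correct_qcrlsc(dirty, design)
        qc = np.array(design.is_qc)

        def qc_cv(m):
            vals = m.values[:, qc]
            return np.nanmedian(vals.std(1, ddof=1) / vals.mean(1))

        assert 1 - qc_cv(out) / qc_cv(dirty) >= 0.5


class TestGradientLength:
    def test_identical_samples_give_zero(self):
        assert gradient_length(np.tile([5.0, 1.0, 2.0], (4, 1))) == pytest.approx(0.0, abs=1e-8)

    def test_unimodal_turnover_exceeds_three(self):
        grad = np.linspace(0, 10, 30)
        opt = np.linspace(0, 10, 50)
        m = np.exp(-((grad[:, None] - opt[None, :]) ** 2) / 2.0) * 100
        assert gradient_length(m) > 3.0

    def test_compact_data_below_three(self):
        rng = np.random.default_rng(7)
        m = np.abs(rng.normal(100, 10, size=(30, 50)))
        assert gradient_length(m) < 3.0

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            gradient_length(np.array([[1.0, -1.0], [1.0, 2.0]]))

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            gradient_length(np.array([[0.0, 0.0], [1.0, 2.0]]))


class TestEvaluation:
    def test_ordination_follows_gradient_length_rule(self):
        # long-gradient composition -> PCA; compact intensity table -> CCA
        grad = np.linspace(0, 10, 24)
        opt = np.linspace(0, 10, 40)
        long_m = pd.DataFrame(
            (np.exp(-((grad[:, None] - opt[None, :]) ** 2) / 2.0) * 100 + 0.1).T
        )
        design = BatchDesign(
            sample_ids=[f"s{i}" for i in range(24)],
            batch=["B1"] * 12 + ["B2"] * 12,
            group=["A", "B"] * 12,
            is_qc=[False] * 24,
            injection_order=list(range(1, 25)),
        )
        long_m.columns = design.sample_ids
        _, ordination = evaluate_correction(long_m, design)
        assert ordination == "PCA"
        table, design2, _ = simulate_batched_table(
            n_features=60, n_samples=24, batches=2, seed=0
        )
        assert gradient_length(table.values.T) < 3.0
        _, ordination2 = evaluate_correction(table, design2)
        assert ordination2 == "CCA"

    def test_score_monotone_in_planted_shift(self):
        # same per-feature shift pattern, scaled to three strengths
        _, design, clean = simulate_batched_table(
            n_features=120, n_samples=48, batches=2, batch_shift=[1, 1], qc_every=6, seed=11
        )
        rng = np.random.default_rng(5)
        pattern = rng.lognormal(0.0, 0.3, 120)
        b2 = np.array([b == "B2" for b in design.batch])
        scores = []
        for shift in (1.3, 2.0, 3.2):
            dirty = clean.copy()
            dirty.loc[:, b2] = clean.loc[:, b2].mul(shift * pattern, axis=0)
            scores.append(evaluate_correction(dirty, design)[0])
        assert scores[0] < scores[1] < scores[2]
        assert evaluate_correction(clean, design)[0] < scores[2]


class TestSelector:
    def test_clean_data_selects_none(self):
        _, design, clean = simulate_batched_table(
            n_features=120, n_samples=48, batches=2, batch_shift=[1, 1], qc_every=6, seed=21
        )
        res = select_best_correction(clean, design)
        assert res.method == "none"

    def test_svd_bias_selects_eigenms(self):
        _, design, clean = simulate_batched_table(
            n_features=120, n_samples=48, batches=2, batch_shift=[1, 1], qc_every=6, seed=11
        )
        rng = np.random.default_rng(2)
        u = rng.normal(1.0, 0.4, 120)
        v = np.sin(np.arange(48) * 1.3)
        res = select_best_correction(clean * np.exp(0.6 * np.outer(u, v)), design)
        assert res.method == "eigenms"

    def test_batch_shift_triggers_correction(self):
        table, design, _ = simulate_batched_table(
            n_features=120, n_samples=48, batches=2, batch_shift=[1, 2.5], qc_every=6, seed=12
        )
        res = select_best_correction(table, design)
        assert res.method in {"combat", "eigenms"}

    def test_qc_free_design_skips_qcrlsc(self):
        table, design, _ = simulate_batched_table(
            n_features=60, n_samples=24, batches=2, qc_every=0, seed=3
        )
        res = select_best_correction(table, design)
        assert any("qc_rlsc" in line and "skipped" in line for line in res.log)

    def test_winner_never_scores_above_none(self):
        for seed in (12, 21):
            table, design, _ = simulate_batched_table(
                n_features=100, n_samples=48, batches=2, batch_shift=[1, 2], qc_every=6,
                seed=seed
            )
            res = select_best_correction(table, design)
            none_score, _ = evaluate_correction(table, design)
            assert res.score <= none_score + 1e-9
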
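"""Trial sequences, HRF sampling, drift basis and design assembly."""

import numpy as np
import pytest

from emostroop.task_design import (
    HrfSpec,
    build_design_matrix,
    canonical_hrf,
    dct_highpass_basis,
    generate_trial_sequence,
    pair_types_from_conditions,
)


class TestTrialSequence:
    def test_148_trials_counterbalanced(self):
        seq = generate_trial_sequence(n_trials=148, seed=0)
        counts = sorted(seq.pair_type_counts().values())
        assert counts == [36, 37, 37, 37]
        assert len(seq) == 148

    @pytest.mark.parametrize("n_trials", [20, 37, 148])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pair_type_recount_oracle(self, n_trials, seed):
        """Stored pair types equal an independent recount from conditions."""
        seq = generate_trial_sequence(n_trials=n_trials, seed=seed)
        recount = pair_types_from_conditions(seq.conditions)
        assert [t.pair_type for t in seq.trials] == recount

    def test_recount_oracle_many_random_sequences(self):
        for seed in range(300):
            seq = generate_trial_sequence(n_trials=24, seed=seed)
            expected = ["undefined"] + [
                a.lower() + b
                for a, b in zip(seq.conditions[:-1], seq.conditions[1:])
            ]
            assert [t.pair_type for t in seq.trials] == expected

    def test_two_trials(self):
        seq = generate_trial_sequence(n_trials=2, seed=3)
        assert seq.trials[0].pair_type == "undefined"
        expected = seq.trials[0].condition.lower() + seq.trials[1].condition
        assert seq.trials[1].pair_type == expected

    def test_onset_gaps_within_isi_bounds(self):
        seq = generate_trial_sequence(148, stimulus_duration_s=1.0,
                                      isi_min_s=3.0, isi_max_s=5.0, seed=4)
        onsets = np.array([t.onset_s for t in seq.trials])
        gaps = np.diff(onsets)
        assert (gaps >= 4.0 - 1e-9).all() and (gaps <= 6.0 + 1e-9).all()
        mean_gap = gaps.mean()
        assert abs(mean_gap - 5.0) < 0.2  # mean SOA ~ stimulus + mean ISI

    def test_deterministic_given_seed(self):
        a = generate_trial_sequence(50, seed=9)
        b = generate_trial_sequence(50, seed=9)
        assert a.to_frame().equals(b.to_frame())

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_trial_sequence(n_trials=1)
        with pytest.raises(ValueError):
            generate_trial_sequence(n_trials=10, isi_min_s=5, isi_max_s=3)

    def test_csv_roundtrip(self, tmp_path):
        seq = generate_trial_sequence(20, seed=1)
        path = tmp_path / "trials.csv"
        seq.to_csv(path)
        back = type(seq).from_csv(path)
        assert [t.condition for t in back.trials] == seq.conditions
        assert np.allclose(
            [t.onset_s for t in back.trials], [t.onset_s for t in seq.trials]
        )


class TestHrf:
    def test_peak_at_six_seconds(self):
        spec = HrfSpec(dt_s=0.05)
        h = canonical_hrf(spec)
        t_peak = np.argmax(h) * spec.dt_s
        assert abs(t_peak - 6.0) <= spec.dt_s + 1e-9

    def test_zero_at_origin_and_unit_peak(self):
        h = canonical_hrf(HrfSpec())
        assert h[0] == 0.0
        assert np.max(np.abs(h)) == pytest.approx(1.0)

    def test_undershoot_outside_window_all_nonnegative(self):
        spec = HrfSpec(dt_s=0.1, peak_delay_s=6.0, undershoot_delay_s=60.0,
                       length_s=8.0)
        h = canonical_hrf(spec)
        assert (h >= -1e-12).all()

    def test_refinement_consistency(self):
        """Halving dt reproduces the coarse samples at shared time points."""
        coarse = canonical_hrf(HrfSpec(dt_s=0.2))
        fine = canonical_hrf(HrfSpec(dt_s=0.1))
        assert np.allclose(fine[::2], coarse, atol=1e-9)

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            HrfSpec(dt_s=0.0)


class TestDctBasis:
    def test_column_count_formula(self):
        basis = dct_highpass_basis(128, 2.0, 1.0 / 128.0)
        assert basis.shape == (128, 4)
        # enumerate DCT frequencies not above cutoff: k / (2 N TR) <= cutoff
        k = np.arange(1, 128)
        expected = int(np.sum(k / (2 * 128 * 2.0) <= 1.0 / 128.0 + 1e-12))
        assert basis.shape[1] == expected

    def test_orthogonality(self):
        basis = dct_highpass_basis(200, 2.0, 1.0 / 64.0)
        gram = basis.T @ basis
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-10

    def test_linear_trend_removal(self):
        """Intercept + drift basis absorbs >98% of a pure linear trend."""
        n = 300
        basis = dct_highpass_basis(n, 2.0, 1.0 / 128.0)
        X = np.column_stack([np.ones(n), basis])
        trend = np.linspace(-1, 1, n)
        beta, _, _, _ = np.linalg.lstsq(X, trend, rcond=None)
        resid = trend - X @ beta
        assert resid.var() < 0.02 * trend.var()

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            dct_highpass_basis(100, 2.0, 0.3)


class TestDesignMatrix:
    def test_regressor_names_complete(self):
        seq = generate_trial_sequence(148, seed=0)
        dm = build_design_matrix(seq, n_scans=390, tr_s=2.0)
        names = set(dm.regressor_names)
        assert {"cC", "iC", "cI", "iI", "error", "intercept"} <= names
        assert {f"mot{i}" for i in range(1, 7)} <= names
        assert any(n.startswith("drift") for n in dm.regressor_names)
        assert dm.values.shape[0] == 390

    def test_single_event_column_proportional_to_hrf(self):
        """A lone cC trial yields a cC column tracking the HRF; others zero."""
        import pandas as pd

        from emostroop.task_design import TrialSequence

        df = pd.DataFrame(
            {
                "onset_s": [0.0],
                "duration_s": [1.0],
                "condition": ["C"],
                "pair_type": ["cC"],
                "correct": [True],
            }
        )
        # single-trial frame needs a second trial to classify pairs; build
        # directly instead
        seq = TrialSequence.from_frame(df)
        with pytest.warns(UserWarning):
            dm = build_design_matrix(seq, n_scans=30, tr_s=2.0)
        for other in ("iC", "cI", "iI", "error"):
            assert np.allclose(dm.column(other), 0.0)
        col = dm.column("cC")
        assert col.max() > 0
        # peak near 6 s post-onset
        assert abs(np.argmax(col) * 2.0 + 1.0 - 6.5) <= 2.0

    def test_shift_and_add_oracle_sticks(self):
        """Stick-event columns equal a direct sum of shifted HRF samples."""
        from emostroop.task_design import canonical_hrf as hrf_fn

        seq = generate_trial_sequence(10, seed=5)
        n_scans, tr = 40, 2.0
        dm = build_design_matrix(seq, n_scans=n_scans, tr_s=tr,
                                 events_as_sticks=True)
        spec = HrfSpec(dt_s=tr / 16)
        kernel = hrf_fn(spec)
        scan_t = (np.arange(n_scans) + 0.5) * tr
        expected = {p: np.zeros(n_scans) for p in ("cC", "iC", "cI", "iI")}
        for t in seq.trials:
            p = "c" + t.condition if t.pair_type == "undefined" else t.pair_type
            onset_idx = int(np.round(t.onset_s / spec.dt_s))
            for i, st in enumerate(scan_t):
                j = int(np.round(st / spec.dt_s)) - onset_idx
                if 0 <= j < len(kernel):
                    expected[p][i] += kernel[j]
        for p, exp in expected.items():
            if exp.any():
                assert np.allclose(dm.column(p), exp, atol=1e-8)

    def test_superposition_boxcars(self):
        """Multi-event boxcar columns are sums of single-event columns."""
        import pandas as pd

        from emostroop.task_design import TrialSequence

        onsets = [0.0, 10.0, 24.0]
        def one(onset):
            df = pd.DataFrame({"onset_s": [onset], "duration_s": [1.0],
                               "condition": ["C"], "pair_type": ["cC"],
                               "correct": [True]})
            with pytest.warns(UserWarning):
                dm = build_design_matrix(TrialSequence.from_frame(df), 30, 2.0)
            return dm.column("cC")

        df = pd.DataFrame({"onset_s": onsets, "duration_s": 1.0,
                           "condition": "C", "pair_type": "cC",
                           "correct": True})
        with pytest.warns(UserWarning):
            combined = build_design_matrix(
                TrialSequence.from_frame(df), 30, 2.0
            ).column("cC")
        assert np.allclose(combined, sum(one(o) for o in onsets), atol=1e-8)

    def test_error_trials_modelled_separately(self):
        seq = generate_trial_sequence(60, seed=2, error_rate=0.3)
        dm = build_design_matrix(seq, n_scans=180, tr_s=2.0)
        assert dm.column("error").any()

    def test_motion_shape_mismatch(self):
        seq = generate_trial_sequence(10, seed=0)
        with pytest.raises(ValueError, match="motion"):
            build_design_matrix(seq, n_scans=40, tr_s=2.0,
                                motion=np.zeros((10, 6)))

    def test_reproducible_from_seed(self):
        a = build_design_matrix(generate_trial_sequence(40, seed=11), 140, 2.0)
        b = build_design_matrix(generate_trial_sequence(40, seed=11), 140, 2.0)
        assert np.array_equal(a.values, b.values)


class TestSequenceProperties:
    """Invariants over arbitrary generator settings."""

    def test_recount_and_balance_invariants_hypothesis(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=60, deadline=None, derandomize=True)
        @given(
            n_trials=st.integers(min_value=2, max_value=60),
            seed=st.integers(min_value=0, max_value=2**31 - 1),
        )
        def check(n_trials, seed):
            seq = generate_trial_sequence(n_trials=n_trials, seed=seed)
            recount = pair_types_from_conditions(seq.conditions)
            assert [t.pair_type for t in seq.trials] == recount
            counts = seq.pair_type_counts()
            assert max(counts.values()) - min(counts.values()) <= 1
            assert sum(counts.values()) == n_trials - 1

        check()
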
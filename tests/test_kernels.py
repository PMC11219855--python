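"""Classification images, normalization and typicality."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from doublepass import (
    ClassificationImage,
    DegenerateKernelError,
    ExperimentLog,
    Kernel,
    ObserverParams,
    SequenceDesign,
    compute_kernel,
    group_average_kernel,
    make_sequence,
    normalize_kernel,
    simulate_experiment,
    truncate_log,
    typicality,
)
from doublepass.kernels import cosine_similarity, kernels_to_frame, write_kernel_matrix


def _simulated_log(sigma, n_trials, seed, stim_config, template):
    design = SequenceDesign(
        n_blocks=2, block_size=max(n_trials // 2, 1), repeat_source_block=0,
        repeat_target_block=1, n_repeats=1,
    )
    rng = np.random.default_rng(seed)
    seq = make_sequence(design, stim_config, rng)[:n_trials]
    return simulate_experiment(ObserverParams(template, sigma), seq, stim_config, rng)


class TestNormalize:
    @pytest.mark.parametrize(
        "weights, expected",
        [
            (np.ones(6), np.ones(6)),  # RMS already 1
            (np.array([2.0, 0, 0, 0, 0, 0]), np.array([np.sqrt(6), 0, 0, 0, 0, 0])),
        ],
    )
    def test_closed_forms(self, weights, expected):
        out = normalize_kernel(Kernel(weights=weights, n_trials=10))
        assert np.allclose(out.weights, expected)
        assert out.normalized

    @given(
        weights=st.lists(
            st.floats(-100, 100), min_size=2, max_size=12
        ).filter(lambda w: np.sqrt(np.mean(np.square(w))) > 1e-6)
    )
    def test_unit_rms_and_idempotence(self, weights):
        k = normalize_kernel(Kernel(weights=np.array(weights), n_trials=1))
        assert k.rms == pytest.approx(1.0, abs=1e-12)
        again = normalize_kernel(k)
        assert np.allclose(again.weights, k.weights, atol=1e-12)

    def test_degenerate_kernel_raises(self):
        with pytest.raises(DegenerateKernelError):
            normalize_kernel(Kernel(weights=np.zeros(6), n_trials=5))
        with pytest.raises(DegenerateKernelError):
            normalize_kernel(Kernel(weights=np.full(6, 1e-12), n_trials=5))


class TestTypicality:
    def test_identity_is_zero(self):
        k = normalize_kernel(Kernel(weights=np.array([1.0, -2, 3, 0.5, 0, 1]), n_trials=1))
        assert typicality(k, k) == 0.0

    def test_sign_flip_scores_four(self):
        k = normalize_kernel(Kernel(weights=np.array([1.0, -2, 3, 0.5, 0.1, 1]), n_trials=1))
        flipped = Kernel(weights=-k.weights, n_trials=1, normalized=True)
        # (2w)^2 averaged over unit-RMS weights: 4 * mean(w^2) = 4
        assert typicality(k, flipped) == pytest.approx(4.0, abs=1e-12)

    def test_unnormalized_inputs_rejected(self):
        raw = Kernel(weights=np.ones(6) * 3, n_trials=1)
        unit = normalize_kernel(Kernel(weights=np.ones(6), n_trials=1))
        with pytest.raises(ValueError):
            typicality(raw, unit)
        with pytest.raises(ValueError):
            typicality(unit, raw)

    def test_symmetric_in_arguments(self):
        a = normalize_kernel(Kernel(weights=np.array([1.0, 2, -1, 0, 3, 1]), n_trials=1))
        b = normalize_kernel(Kernel(weights=np.array([0.0, 1, 1, -2, 0, 2]), n_trials=1))
        assert typicality(a, b) == typicality(b, a)


class TestComputeKernel:
    def test_segment_rule_observer_recovers_its_segment(self, stim_config):
        # rule: pick the stimulus with the larger segment-6 shift
        rng = np.random.default_rng(0)
        design = SequenceDesign(
            n_blocks=2, block_size=5000, repeat_source_block=0,
            repeat_target_block=1, n_repeats=1,
        )
        seq = make_sequence(design, stim_config, rng)
        stimuli = np.stack([t.stimuli for t in seq])
        responses = np.where(stimuli[:, 0, 5] > stimuli[:, 1, 5], 1, 2)
        log = ExperimentLog(trials=seq, responses=responses, config=stim_config)
        k = compute_kernel(log)
        # oracle: E[max - min] of two iid truncated normals, by fresh Monte Carlo
        oracle_rng = np.random.default_rng(123)
        from doublepass.design import _sample_shifts

        a = _sample_shifts(stim_config, oracle_rng, 200_000)
        b = _sample_shifts(stim_config, oracle_rng, 200_000)
        expected6 = np.abs(a - b).mean()
        se6 = np.abs(a - b).std() / np.sqrt(len(seq))
        assert k.weights[5] == pytest.approx(expected6, abs=4 * se6)
        # unassociated segments: within 3 SEs of zero
        per_trial_sd = np.sqrt(2) * stim_config.noise_sd_cents
        assert np.all(np.abs(k.weights[:5]) < 3 * per_trial_sd / np.sqrt(len(seq)))

    def test_coin_flip_responses_give_null_kernel(self, stim_config):
        rng = np.random.default_rng(1)
        design = SequenceDesign(
            n_blocks=2, block_size=5000, repeat_source_block=0,
            repeat_target_block=1, n_repeats=1,
        )
        seq = make_sequence(design, stim_config, rng)
        responses = rng.integers(1, 3, size=len(seq))
        k = compute_kernel(ExperimentLog(trials=seq, responses=responses, config=stim_config))
        se = np.sqrt(2) * stim_config.noise_sd_cents / np.sqrt(len(seq))
        assert np.all(np.abs(k.weights) < 3 * se)

    def test_zero_noise_observer_kernel_aligns_with_template(self, stim_config, template):
        log = _simulated_log(0.0, 100_000, 2, stim_config, template)
        k = normalize_kernel(compute_kernel(log))
        assert cosine_similarity(k.weights, template) > 0.99

    def test_empty_log_rejected(self, stim_config):
        with pytest.raises(ValueError):
            compute_kernel(ExperimentLog(trials=[], responses=[], config=stim_config))

    def test_kernel_amplitude_shrinks_with_internal_noise(self, stim_config, template):
        # expected kernel stays proportional to the template but its
        # amplitude attenuates monotonically as sigma grows
        amplitudes = []
        for sigma in (0.0, 1.0, 2.0, 4.0):
            log = _simulated_log(sigma, 20_000, 3, stim_config, template)
            amplitudes.append(compute_kernel(log).weights @ template)
        assert all(a > b for a, b in zip(amplitudes, amplitudes[1:]))

    def test_recovery_improves_with_trials(self, stim_config, template):
        # monotone in expectation, so average over a few seeded runs
        def mean_cosine(n):
            return np.mean(
                [
                    cosine_similarity(
                        normalize_kernel(
                            compute_kernel(
                                _simulated_log(1.0, n, 40 + s, stim_config, template)
                            )
                        ).weights,
                        template,
                    )
                    for s in range(5)
                ]
            )

        cosines = [mean_cosine(n) for n in (150, 1000, 10_000)]
        assert cosines[0] < cosines[1] < cosines[2]


class TestGroupAverage:
    def _kernels(self):
        ws = [np.array([1.0, 0, 0, 0, 1, 2]), np.array([0.0, 1, 0, 0, 1, 2]),
              np.array([1.0, 1, 0, 0, 0, 2])]
        return [normalize_kernel(Kernel(weights=w, n_trials=150)) for w in ws]

    def test_average_is_renormalized_mean(self):
        kernels = self._kernels()
        avg = group_average_kernel(kernels)
        mean = np.mean([k.weights for k in kernels], axis=0)
        assert np.allclose(avg.weights, mean / np.sqrt(np.mean(mean**2)))
        assert avg.rms == pytest.approx(1.0, abs=1e-12)

    def test_leave_one_out_excludes_that_kernel(self):
        kernels = self._kernels()
        loo = group_average_kernel(kernels, leave_out=0)
        mean = np.mean([k.weights for k in kernels[1:]], axis=0)
        assert np.allclose(loo.weights, mean / np.sqrt(np.mean(mean**2)))

    def test_requires_normalized_inputs(self):
        with pytest.raises(ValueError):
            group_average_kernel([Kernel(weights=np.ones(6), n_trials=1)])

    def test_shared_template_cohort_typicality_vanishes(self, stim_config, template):
        # zero-noise observers sharing one template: pairwise typicality -> 0
        kernels = [
            normalize_kernel(
                compute_kernel(_simulated_log(0.0, 20_000, 10 + i, stim_config, template))
            )
            for i in range(3)
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                assert typicality(kernels[i], kernels[j]) < 0.01


class TestUtilities:
    def test_truncate_log_keeps_presentation_order(self, stim_config, design, template):
        log = _simulated_log(1.0, 150, 5, stim_config, template)
        short = truncate_log(log, 100)
        assert len(short) == 100
        assert np.array_equal(short.responses, log.responses[:100])
        assert short.trials[0] is log.trials[0]
        with pytest.raises(ValueError):
            truncate_log(log, 0)

    def test_estimator_matches_functional_path(self, stim_config, template):
        log = _simulated_log(1.0, 500, 6, stim_config, template)
        ci = ClassificationImage().fit(log.stimuli, log.responses)
        expected = normalize_kernel(compute_kernel(log))
        assert np.allclose(ci.weights_, expected.weights)
        assert ci.n_trials_ == 500
        raw = ClassificationImage(normalize=False).fit_log(log)
        assert np.allclose(raw.weights_, compute_kernel(log).weights)
        # sklearn contract: params round-trip and clone
        assert clone(ci).get_params() == ci.get_params()

    def test_estimator_input_validation(self):
        with pytest.raises(ValueError):
            ClassificationImage().fit(np.zeros((3, 3, 6)), np.ones(3, dtype=int))
        with pytest.raises(ValueError):
            ClassificationImage().fit(np.zeros((3, 2, 6)), np.array([1, 2, 3]))

    def test_table_writers(self, tmp_path):
        import pandas as pd

        k = normalize_kernel(Kernel(weights=np.array([1.0, 2, 3, 4, 5, 6]), n_trials=1))
        df = kernels_to_frame(k)
        assert list(df.columns) == ["segment", "weight"]
        assert len(df) == 6
        path = tmp_path / "matrix.csv"
        write_kernel_matrix([k, k], ["a", "b"], path)
        back = pd.read_csv(path, index_col="participant")
        assert back.shape == (2, 6)
        assert np.allclose(back.loc["a"].to_numpy(), k.weights)
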
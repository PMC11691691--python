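"""Behavioral RDM estimation, stimulus models, and dependent correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from hemidyn.behavior import (RDM, build_model_rdms, build_rdm_from_triplets,
                              compare_dependent_correlations, correlate_rdms,
                              neural_behavior_timecourse)
from hemidyn.synth import StimulusSet, generate_triplet_responses
from tests.conftest import make_rdm_series


def _responses(rows):
    return pd.DataFrame(rows, columns=["participant", "trial", "stim_a", "stim_b",
                                       "stim_c", "chosen"])


class TestBuildRDM:
    def test_single_trial_coding(self):
        rdm = build_rdm_from_triplets(_responses([(1, 1, 1, 2, 3, "a")]), 4)
        assert rdm.values[0, 1] == 1.0 and rdm.values[0, 2] == 1.0
        assert rdm.values[1, 2] == 0.0
        assert np.isnan(rdm.values[0, 3])
        assert rdm.pair_counts[0, 1] == 1 and rdm.pair_counts[0, 3] == 0

    def test_opposite_choices_average_to_half(self):
        rdm = build_rdm_from_triplets(
            _responses([(1, 1, 1, 2, 3, "a"), (1, 2, 1, 2, 3, "b")]), 3)
        assert rdm.values[0, 1] == 1.0          # both trials separate 1 and 2
        assert rdm.values[0, 2] == 0.5
        assert rdm.values[1, 2] == 0.5

    def test_uniform_choices_converge_to_two_thirds(self):
        """Under uniform choice each pair member is odd-one-out w.p. 2/3."""
        flat = np.zeros((10, 10))
        resp = generate_triplet_responses([flat], [1.0], 5, 10000,
                                          decision_noise=1.0, seed=13)
        rdm = build_rdm_from_triplets(resp, 10)
        cells = rdm.pair_vector()
        assert abs(np.nanmean(cells) - 2 / 3) < 0.01
        assert np.nanmax(np.abs(cells - 2 / 3)) < 0.08

    def test_low_noise_recovers_latent_structure(self):
        rng = np.random.default_rng(1)
        d = rng.random((12, 12))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        resp = generate_triplet_responses([d], [1.0], 5, 10000,
                                          decision_noise=0.01, seed=17)
        rdm = build_rdm_from_triplets(resp, 12)
        rho = correlate_rdms(rdm, RDM(values=d)).rho
        assert rho > 0.85

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            build_rdm_from_triplets(_responses([(1, 1, 2, 2, 3, "a")]), 4)


class TestModels:
    def test_binary_model_structure(self):
        s = StimulusSet.default()
        models = build_model_rdms(s)
        img, con = models["image_model"].values, models["concept_model"].values
        # two images of different concepts: same modality, different concept
        face_img = s.table.query("modality=='image' and concept=='face'")["stimulus_id"].iloc[0]
        tree_img = s.table.query("modality=='image' and concept=='tree'")["stimulus_id"].iloc[0]
        face_word = s.table.query("modality=='word' and concept=='face'")["stimulus_id"].iloc[0]
        assert img[face_img - 1, tree_img - 1] == 0.0
        assert con[face_img - 1, tree_img - 1] == 1.0
        assert img[face_img - 1, face_word - 1] == 1.0
        assert con[face_img - 1, face_word - 1] == 0.0
        assert img[face_img - 1, face_img - 1] == 0.0
        assert set(np.unique(img)) == {0.0, 1.0}


class TestCorrelate:
    def test_identity_and_monotone_invariance(self):
        rng = np.random.default_rng(2)
        m = rng.random((8, 8))
        m = (m + m.T) / 2
        a = RDM(values=m)
        assert correlate_rdms(a, a).rho == pytest.approx(1.0)
        b = RDM(values=np.exp(2 * m))
        assert correlate_rdms(a, b).rho == pytest.approx(1.0)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(3)
        a = rng.random((7, 7))
        b = rng.random((7, 7))
        a, b = (a + a.T) / 2, (b + b.T) / 2
        assert correlate_rdms(RDM(values=a), RDM(values=b)).rho == \
            correlate_rdms(RDM(values=b), RDM(values=a)).rho

    def test_model_cross_correlation_matches_direct_spearman(self):
        models = build_model_rdms(StimulusSet.default())
        res = correlate_rdms(models["image_model"], models["concept_model"])
        iu = np.triu_indices(36, k=1)
        want = spearmanr(models["image_model"].values[iu],
                         models["concept_model"].values[iu]).statistic
        assert res.n_pairs == 630
        assert res.rho == pytest.approx(want, abs=1e-12)

    def test_permutation_p_value_bounds(self):
        models = build_model_rdms(StimulusSet.make(("bird", "fish"), 2, 2))
        res = correlate_rdms(models["image_model"], models["concept_model"],
                             n_permutations=99, seed=0)
        assert 1 / 100 <= res.p_value <= 1.0

    def test_insufficient_cells_rejected(self):
        m = np.full((4, 4), np.nan)
        m[0, 1] = m[1, 0] = 0.3
        with pytest.raises(ValueError, match="3 complete pairs"):
            correlate_rdms(RDM(values=m), RDM(values=np.zeros((4, 4))))


class TestSteiger:
    def test_equal_correlations_give_zero(self):
        assert compare_dependent_correlations(0.5, 0.5, 0.3, 100).z == 0.0

    def test_antisymmetry(self):
        a = compare_dependent_correlations(0.8, 0.3, 0.6, 630).z
        b = compare_dependent_correlations(0.3, 0.8, 0.6, 630).z
        assert a == pytest.approx(-b, abs=1e-12)

    def test_matches_independent_formula_transcription(self):
        """Direct transcription of the dependent-correlation z formula."""
        import math

        def oracle(r1, r2, r12, n):
            z1 = 0.5 * math.log((1 + r1) / (1 - r1))
            z2 = 0.5 * math.log((1 + r2) / (1 - r2))
            rm2 = ((r1 + r2) / 2.0) ** 2
            psi = (r12 * (1 - 2 * rm2) - 0.5 * rm2 * (1 - 2 * rm2 - r12 * r12))
            s = psi / ((1 - rm2) ** 2)
            return (z1 - z2) * math.sqrt((n - 3) / (2 - 2 * s))

        cases = [(0.8, 0.3, 0.6, 630), (0.81, 0.59, 0.61, 630),
                 (-0.4, 0.2, 0.1, 50), (0.95, 0.9, 0.85, 200)]
        for r1, r2, r12, n in cases:
            got = compare_dependent_correlations(r1, r2, r12, n).z
            assert got == pytest.approx(oracle(r1, r2, r12, n), abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_dependent_correlations(1.0, 0.3, 0.2, 100)
        with pytest.raises(ValueError):
            compare_dependent_correlations(0.5, 0.3, 0.2, 3)


class TestNeuralBehavior:
    def test_constant_matching_series_gives_unit_correlation(self):
        rng = np.random.default_rng(4)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        neural = make_rdm_series(np.repeat(m[:, :, None], 5, axis=2))
        res = neural_behavior_timecourse(neural, RDM(values=m))
        np.testing.assert_allclose(res.rho, 1.0, atol=1e-12)

    def test_mismatched_stimuli_rejected(self):
        neural = make_rdm_series(np.zeros((4, 4, 3)))
        with pytest.raises(ValueError, match="stimulus sets"):
            neural_behavior_timecourse(neural, RDM(values=np.zeros((5, 5))))

    def test_image_weighted_patterns_prefer_image_model_series(self):
        """Epochs whose latent geometry carries only the image/word factor
        correlate more with the image model than the concept model in the
        signal window."""
        from hemidyn.decode import LEFT_CLUSTER, balance_word_trials, pairwise_decode
        from hemidyn.synth import SimulationConfig, StimulusSet, generate_design, \
            generate_epochs

        stimuli = StimulusSet.make(("bird", "fish", "tree"), 2, 2)
        cfg = SimulationConfig(n_participants=1, n_single_sequences=12,
                               n_dual_sequences=0, epoch_window=(-50, 250),
                               snr=1.0, w_image=1.0, w_concept=0.0, w_unique=0.3,
                               seed=19)
        design = generate_design(cfg, stimuli)
        balanced = balance_word_trials(design, stimuli, seed=19)
        epochs = generate_epochs(cfg, balanced, stimuli)
        neural = pairwise_decode(epochs, LEFT_CLUSTER, "single", "RVF", n_folds=12)
        models = build_model_rdms(stimuli)
        rho_img = neural_behavior_timecourse(neural, models["image_model"]).rho
        rho_con = neural_behavior_timecourse(neural, models["concept_model"]).rho
        window = (epochs.times >= 90) & (epochs.times <= 200)
        assert np.nanmean(rho_img[window]) > np.nanmean(rho_con[window]) + 0.2
        assert np.nanmean(rho_img[window]) > 0.3
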
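"""Decoder contracts: balancing, cross-validation, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from hemidyn.decode import (LEFT_CLUSTER, RIGHT_CLUSTER, ElectrodeCluster,
                            balance_word_trials, collapse_contra_ipsi,
                            mean_accuracy, n_pairwise_contrasts, pairwise_decode,
                            stimulus_pairs)
from hemidyn.synth import (EpochSet, SimulationConfig, StimulusSet,
                           generate_design)


def test_pair_enumeration_counts():
    assert n_pairwise_contrasts(36) == 630
    assert len(stimulus_pairs(StimulusSet.default().ids)) == 630
    assert len(stimulus_pairs([1, 2, 3])) == 3


class TestBalanceWordTrials:
    def test_full_design_subsamples_words_to_48(self):
        cfg = SimulationConfig(n_participants=1, seed=1)
        stimuli = StimulusSet.default()
        out = balance_word_trials(generate_design(cfg, stimuli), stimuli, seed=1)
        for condition in ("single", "dual"):
            for side, col in (("lvf", "lvf_stimulus"), ("rvf", "rvf_stimulus")):
                kept = out[(out["condition"] == condition) & out[f"use_{side}"]]
                counts = kept[col].value_counts()
                assert all(counts[s] == 48 for s in stimuli.word_ids)
                assert all(counts[s] == 48 for s in stimuli.image_ids)

    def test_already_balanced_is_identity(self, stimuli12):
        cfg = SimulationConfig(n_participants=1, n_single_sequences=2,
                               n_dual_sequences=0, seed=2)
        first = balance_word_trials(generate_design(cfg, stimuli12), stimuli12, seed=2)
        retained = first[first["use_lvf"] | first["use_rvf"]]
        again = balance_word_trials(retained.drop(columns=["use_lvf", "use_rvf"])
                                    .reset_index(drop=True), stimuli12, seed=5)
        # already at target: nothing new dropped on either side
        assert again["use_lvf"].equals(again["lvf_stimulus"].notna())
        assert again["use_rvf"].equals(again["rvf_stimulus"].notna())

    def test_insufficient_word_repeats_error(self, stimuli12):
        cfg = SimulationConfig(n_participants=1, n_single_sequences=1,
                               n_dual_sequences=0, seed=3)
        d = generate_design(cfg, stimuli12)
        word = stimuli12.word_ids[0]
        drop = d.index[d["lvf_stimulus"] == word][:5]
        d2 = pd.concat([d.drop(index=drop)] * 2, ignore_index=True)
        # images doubled to 4/hemifield; the mutilated word has only 2+... < target
        with pytest.raises(ValueError, match=str(word)):
            balance_word_trials(d2, stimuli12, seed=0)


def _toy_epochs(n_stim=2, n_seq=4, trials_per=2, n_ch=2, n_t=15, sep=0.0, seed=0,
                channels=None):
    """Hand-built single-participant EpochSet: Gaussian classes, optional separation."""
    rng = np.random.default_rng(seed)
    rows = []
    data = []
    for seq in range(n_seq):
        for s in range(1, n_stim + 1):
            for _ in range(trials_per):
                x = rng.standard_normal((n_ch, n_t))
                x += sep * s  # class-dependent offset on every channel
                data.append(x)
                rows.append((1, "single", seq, len(rows) + 1, pd.NA, s, 0))
    meta = pd.DataFrame(rows, columns=["participant", "condition", "sequence_index",
                                       "trial_index", "lvf_stimulus", "rvf_stimulus",
                                       "onset_time"])
    meta["lvf_stimulus"] = meta["lvf_stimulus"].astype("Int64")
    meta["rvf_stimulus"] = meta["rvf_stimulus"].astype("Int64")
    if channels is None:
        names = [f"ch{i}" for i in range(n_ch)]
        channels = pd.DataFrame({"name": names, "cluster": ["left"] * n_ch})
    return EpochSet(np.stack(data), meta, channels, np.arange(n_t))


def test_no_information_gives_chance_accuracy():
    e = _toy_epochs(n_stim=2, n_seq=8, trials_per=4, n_t=40, sep=0.0, seed=1)
    cluster = ElectrodeCluster("left", ("ch0", "ch1"))
    rdm = pairwise_decode(e, cluster, "single", "RVF", n_folds=4)
    acc = mean_accuracy(rdm).values
    assert abs(acc.mean() - 0.5) < 0.03
    assert acc.min() >= 0.0 and acc.max() <= 1.0


def test_separated_classes_match_nearest_centroid_oracle():
    """Spherical shared-covariance classes: LDA reduces to nearest class mean."""
    e = _toy_epochs(n_stim=2, n_seq=4, trials_per=5, n_t=10, sep=1.2, seed=2)
    cluster = ElectrodeCluster("left", ("ch0", "ch1"))
    # full shrinkage toward the scaled identity encodes the spherical premise
    rdm = pairwise_decode(e, cluster, "single", "RVF", n_folds=4, shrinkage=1.0)

    # brute-force nearest-centroid on the same folds
    meta = e.trial_meta
    labels = meta["rvf_stimulus"].to_numpy(dtype=int)
    folds = meta["sequence_index"].to_numpy() % 4
    correct = np.zeros(e.data.shape[2])
    total = 0
    for f in range(4):
        tr, te = folds != f, folds == f
        mus = {s: e.data[tr & (labels == s)].mean(axis=0) for s in (1, 2)}
        for i in np.nonzero(te)[0]:
            d1 = ((e.data[i] - mus[1]) ** 2).sum(axis=0)
            d2 = ((e.data[i] - mus[2]) ** 2).sum(axis=0)
            pred = np.where(d1 <= d2, 1, 2)
            correct += pred == labels[i]
            total += 1
    oracle = correct / total
    assert np.abs(rdm.values[0, 1] - oracle).max() <= 0.011


def test_matches_hand_computed_fisher_discriminant():
    """With shrinkage disabled, decisions equal the explicit Fisher rule."""
    for seed in range(10):
        e = _toy_epochs(n_stim=2, n_seq=2, trials_per=6, n_t=4, sep=0.4, seed=seed)
        cluster = ElectrodeCluster("left", ("ch0", "ch1"))
        rdm = pairwise_decode(e, cluster, "single", "RVF", n_folds=2, shrinkage=None)

        meta = e.trial_meta
        labels = meta["rvf_stimulus"].to_numpy(dtype=int)
        folds = meta["sequence_index"].to_numpy() % 2
        correct = np.zeros(e.data.shape[2])
        total = 0
        for f in range(2):
            tr, te = folds != f, folds == f
            for t in range(e.data.shape[2]):
                x1 = e.data[tr & (labels == 1), :, t]
                x2 = e.data[tr & (labels == 2), :, t]
                mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
                xc = np.vstack([x1 - mu1, x2 - mu2])
                cov = xc.T @ xc / len(xc)
                w = np.linalg.solve(cov, mu1 - mu2)
                c = w @ (mu1 + mu2) / 2
                for i in np.nonzero(te)[0]:
                    pred = 1 if e.data[i, :, t] @ w - c >= 0 else 2
                    correct[t] += pred == labels[i]
            total += te.sum()
        np.testing.assert_allclose(rdm.values[0, 1], correct / total, atol=1e-12)


def test_matches_sklearn_lda_accuracy():
    """Cross-check against scikit-learn's LDA on the same folds (one time point)."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    e = _toy_epochs(n_stim=2, n_seq=4, trials_per=6, n_t=3, sep=0.5, seed=7)
    cluster = ElectrodeCluster("left", ("ch0", "ch1"))
    rdm = pairwise_decode(e, cluster, "single", "RVF", n_folds=4, shrinkage=None)

    labels = e.trial_meta["rvf_stimulus"].to_numpy(dtype=int)
    folds = e.trial_meta["sequence_index"].to_numpy() % 4
    for t in range(3):
        correct = total = 0
        for f in range(4):
            tr, te = folds != f, folds == f
            clf = LinearDiscriminantAnalysis(solver="lsqr")
            clf.fit(e.data[tr, :, t], labels[tr])
            correct += (clf.predict(e.data[te, :, t]) == labels[te]).sum()
            total += te.sum()
        assert abs(rdm.values[0, 1, t] - correct / total) <= 1e-6


def test_fold_independence_under_trial_reordering():
    """Permuting trials within the epochs leaves fold-pooled results unchanged."""
    e = _toy_epochs(n_stim=3, n_seq=4, trials_per=3, n_t=8, sep=0.6, seed=3)
    cluster = ElectrodeCluster("left", ("ch0", "ch1"))
    a = pairwise_decode(e, cluster, "single", "RVF", n_folds=4)
    perm = np.random.default_rng(0).permutation(e.data.shape[0])
    e2 = EpochSet(e.data[perm], e.trial_meta.iloc[perm].reset_index(drop=True),
                  e.channels, e.times)
    b = pairwise_decode(e2, cluster, "single", "RVF", n_folds=4)
    np.testing.assert_array_equal(a.values, b.values)


def test_symmetry_and_pair_count(high_snr_epochs, stimuli12):
    cfg, epochs = high_snr_epochs
    rdm = pairwise_decode(epochs, LEFT_CLUSTER, "single", "RVF", n_folds=12)
    assert rdm.n_pairs == n_pairwise_contrasts(12) == 66
    v = np.nan_to_num(rdm.values)
    np.testing.assert_array_equal(v, v.transpose(1, 0, 2))
    assert np.isnan(rdm.values[np.arange(12), np.arange(12)]).all()
    # sustained above-chance accuracy after the contralateral onset
    acc = mean_accuracy(rdm).values
    sig = acc[(epochs.times >= cfg.contra_onset) & (epochs.times <= 180)]
    assert sig.mean() > 0.6
    base = acc[epochs.times < 0]
    assert abs(base.mean() - 0.5) < 0.03


def test_stimulus_absent_from_fold_errors():
    e = _toy_epochs(n_stim=2, n_seq=4, trials_per=1, n_t=5, seed=4)
    # remove stimulus 2 from sequence 0 entirely
    keep = ~((e.trial_meta["sequence_index"] == 0)
             & (e.trial_meta["rvf_stimulus"] == 2))
    e2 = EpochSet(e.data[keep.to_numpy()], e.trial_meta[keep].reset_index(drop=True),
                  e.channels, e.times)
    with pytest.raises(ValueError, match="absent from fold"):
        pairwise_decode(e2, ElectrodeCluster("left", ("ch0", "ch1")),
                        "single", "RVF", n_folds=4)


def test_missing_cluster_channel_errors():
    e = _toy_epochs()
    with pytest.raises(KeyError, match="O1"):
        pairwise_decode(e, LEFT_CLUSTER, "single", "RVF", n_folds=4)


class TestCollapse:
    def test_arithmetic(self):
        res = {("left", "RVF"): np.full(3, 0.6), ("right", "LVF"): np.full(3, 0.5),
               ("left", "LVF"): np.full(3, 0.52), ("right", "RVF"): np.full(3, 0.54)}
        out = collapse_contra_ipsi(res)
        np.testing.assert_allclose(out["contralateral"], 0.55)
        np.testing.assert_allclose(out["ipsilateral"], 0.53)

    def test_identical_inputs_pass_through(self):
        arr = np.linspace(0, 1, 5)
        out = collapse_contra_ipsi({k: arr for k in
                                    [("left", "RVF"), ("right", "LVF"),
                                     ("left", "LVF"), ("right", "RVF")]})
        np.testing.assert_array_equal(out["contralateral"], arr)
        np.testing.assert_array_equal(out["ipsilateral"], arr)

    def test_missing_combination_errors(self):
        with pytest.raises(KeyError, match="missing"):
            collapse_contra_ipsi({("left", "RVF"): np.zeros(3)})


def test_ipsilateral_accuracy_monotone_in_retention_and_gain():
    """More transferred pattern content -> better ipsilateral decoding."""
    stimuli = StimulusSet.make(("bird", "fish"), 1, 1)  # 4 stimuli

    def ipsi_acc(retention, gain):
        cfg = SimulationConfig(n_participants=1, n_single_sequences=4,
                               n_dual_sequences=0, epoch_window=(-50, 300),
                               snr=8.0, retention=retention, ipsi_gain=gain,
                               pattern_dim=8, seed=21)
        from hemidyn.synth import generate_epochs
        e = generate_epochs(cfg, generate_design(cfg, stimuli), stimuli)
        rdm = pairwise_decode(e, RIGHT_CLUSTER, "single", "RVF", n_folds=4)
        acc = mean_accuracy(rdm).values
        return acc[(e.times >= 100) & (e.times <= 220)].mean()

    by_retention = [ipsi_acc(r, 1.0) for r in (0.125, 0.5, 1.0)]
    assert by_retention[0] <= by_retention[1] + 0.02 <= by_retention[2] + 0.04
    assert by_retention[2] > by_retention[0]
    by_gain = [ipsi_acc(1.0, g) for g in (0.15, 0.5, 1.0)]
    assert by_gain[0] <= by_gain[1] + 0.02 <= by_gain[2] + 0.04
    assert by_gain[2] > by_gain[0]
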
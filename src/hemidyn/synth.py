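"""Synthetic lateralized-EEG experiment generator.

Emulates a rapid serial visual presentation study in which 36 stimuli
(24 object images: 6 concepts x 4 exemplars; 12 word labels: 6 concepts x
2 case variants) are flashed to the left or right visual hemifield while
multichannel EEG-like activity is recorded from occipito-temporal electrode
clusters over each hemisphere.

Ground-truth structure injected by the generator:

* every stimulus has a latent activation pattern per participant; the
  hemisphere *contralateral* to the stimulated hemifield receives that
  pattern convolved with a smooth response bump starting at ``contra_onset``;
* the *ipsilateral* hemisphere receives a rank-reduced copy (a fraction
  ``retention`` of the pattern dimensions), attenuated by ``ipsi_gain`` and
  delayed by ``transfer_delay`` — a controllable stand-in for callosal
  transfer;
* in dual-hemifield trials both stimuli contribute and all pattern signal
  after ``interference_onset`` is attenuated by ``interference_attenuation``;
* additive AR(1) Gaussian noise sets the signal-to-noise ratio.

Because every downstream estimate (decoding onsets, transfer-delay profiles,
variance partitions) has a known injected value, the full analysis stack can
be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "CONCEPTS",
    "LEFT_CLUSTER_CHANNELS",
    "RIGHT_CLUSTER_CHANNELS",
    "StimulusSet",
    "SimulationConfig",
    "EpochSet",
    "generate_design",
    "generate_epochs",
    "generate_triplet_responses",
]

CONCEPTS = ("bird", "fish", "tree", "boat", "face", "tool")

# Occipito-temporal 10-20 clusters used for the hemisphere analyses.
LEFT_CLUSTER_CHANNELS = ("O1", "PO3", "PO7", "P3", "P5", "P7")
RIGHT_CLUSTER_CHANNELS = ("O2", "PO4", "PO8", "P4", "P6", "P8")
OTHER_CHANNELS = ("Oz", "POz")

# Stage tags keep the RNG streams of the generator's phases independent.
_STAGE_DESIGN = 11
_STAGE_EPOCHS = 12
_STAGE_TRIPLETS = 13


class StimulusSet:
    """The experimental stimulus inventory.

    Stimuli are identified by contiguous integer ids starting at 1; each is an
    image exemplar or a word (case) variant of one of six object concepts.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"stimulus_id", "modality", "concept", "exemplar"}
        if not required.issubset(table.columns):
            raise ValueError(f"stimulus table needs columns {sorted(required)}")
        table = table.reset_index(drop=True)
        ids = table["stimulus_id"].to_numpy()
        if not np.array_equal(ids, np.arange(1, len(table) + 1)):
            raise ValueError("stimulus_id must be contiguous 1..n")
        if table.duplicated(["modality", "concept", "exemplar"]).any():
            raise ValueError("(modality, concept, exemplar) must be unique")
        if not set(table["modality"]).issubset({"image", "word"}):
            raise ValueError("modality must be 'image' or 'word'")
        self.table = table

    @classmethod
    def default(cls) -> "StimulusSet":
        """The full 36-stimulus set: 6 concepts x 4 image exemplars + 2 word variants."""
        return cls.make(CONCEPTS, n_image_exemplars=4, n_word_variants=2)

    @classmethod
    def make(
        cls,
        concepts: Sequence[str] = CONCEPTS,
        n_image_exemplars: int = 4,
        n_word_variants: int = 2,
    ) -> "StimulusSet":
        rows = []
        for concept in concepts:
            for ex in range(1, n_image_exemplars + 1):
                rows.append(("image", concept, ex))
        for concept in concepts:
            for ex in range(1, n_word_variants + 1):
                rows.append(("word", concept, ex))
        table = pd.DataFrame(rows, columns=["modality", "concept", "exemplar"])
        table.insert(0, "stimulus_id", np.arange(1, len(table) + 1))
        return cls(table)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["stimulus_id"].to_numpy()

    @property
    def image_ids(self) -> np.ndarray:
        return self.table.loc[self.table["modality"] == "image", "stimulus_id"].to_numpy()

    @property
    def word_ids(self) -> np.ndarray:
        return self.table.loc[self.table["modality"] == "word", "stimulus_id"].to_numpy()


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Times are in ms relative to stimulus onset; the sample rate is fixed at
    1000 Hz (1 ms resolution).

    Parameters
    ----------
    n_participants, n_single_sequences, n_dual_sequences
        Study size: 20 participants, 24 single-hemifield and 12 dual-hemifield
        sequences of 192 trials each.
    contra_onset
        Latency (ms) at which stimulus-specific signal appears in the
        contralateral cluster (default 80 ms, matching typical lateralized
        decoding onsets).
    transfer_delay
        Interhemispheric transfer delay Δ (ms) added for the ipsilateral copy
        (default 20 ms, mid-range of occipital transfer-time estimates).
    retention
        Fraction ρ of latent pattern dimensions carried to the ipsilateral
        hemisphere (the ipsilateral copy keeps the first ``ceil(ρ·pattern_dim)``
        components); < 1 makes ipsilateral information a strict subset.
    ipsi_gain
        Amplitude scaling γ of the ipsilateral copy.  The empirical
        ipsi/contra amplitude ratio is not constrained by lateralized-ERP
        reports; 0.6 is a free choice of this generator.
    interference_onset, interference_attenuation
        In dual trials, pattern signal after ``interference_onset`` (ms) is
        multiplied by β = ``interference_attenuation`` (< 1 degrades late
        representations, emulating interference between competing stimuli).
    snr
        Ratio of RMS signal to RMS noise, measured over the two cluster
        channel groups within 0–500 ms.  ``snr=0`` yields pure-noise epochs.
    pattern_dim
        Latent pattern components per stimulus per hemisphere.
    noise_autocorr
        AR(1) coefficient of the additive channel noise.
    w_image, w_concept, w_unique
        Variance weights mixing a shared image/word factor, a shared concept
        factor, and a stimulus-unique component into the latent patterns; with
        positive ``w_image``/``w_concept`` the neural RDM geometry carries the
        corresponding model structure.
    """

    n_participants: int = 20
    n_single_sequences: int = 24
    n_dual_sequences: int = 12
    sample_rate: int = 1000
    epoch_window: tuple[int, int] = (-100, 800)
    contra_onset: int = 80
    transfer_delay: int = 20
    retention: float = 0.6
    ipsi_gain: float = 0.6
    interference_onset: int = 150
    interference_attenuation: float = 0.8
    snr: float = 0.5
    pattern_dim: int = 8
    n_channels_per_cluster: int = 6
    noise_autocorr: float = 0.9
    kernel_width: int = 100
    w_image: float = 0.0
    w_concept: float = 0.0
    w_unique: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.sample_rate != 1000:
            raise ValueError("sample_rate is fixed at 1000 Hz (1 ms resolution)")
        if self.n_participants < 1 or self.n_single_sequences < 0 or self.n_dual_sequences < 0:
            raise ValueError("counts must be positive")
        lo, hi = self.epoch_window
        if lo >= hi:
            raise ValueError("epoch_window must be increasing")
        if self.transfer_delay < 0:
            raise ValueError("transfer_delay must be >= 0")
        if self.contra_onset + self.transfer_delay >= hi:
            raise ValueError("contra_onset + transfer_delay must fall before the epoch end")
        if not (0.0 <= self.retention <= 1.0):
            raise ValueError("retention must lie in [0, 1]")
        if not (0.0 < self.ipsi_gain <= 1.0):
            raise ValueError("ipsi_gain must lie in (0, 1]")
        if not (0.0 < self.interference_attenuation <= 1.0):
            raise ValueError("interference_attenuation must lie in (0, 1]")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if not (0.0 <= self.noise_autocorr < 1.0):
            raise ValueError("noise_autocorr must lie in [0, 1)")
        if self.pattern_dim < 1 or self.kernel_width < 1:
            raise ValueError("pattern_dim and kernel_width must be positive")
        if not (1 <= self.n_channels_per_cluster <= 6):
            raise ValueError("n_channels_per_cluster must lie in 1..6")
        if min(self.w_image, self.w_concept, self.w_unique) < 0:
            raise ValueError("structure weights must be nonnegative")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["epoch_window"] = list(self.epoch_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimulationConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "epoch_window" in d:
            d["epoch_window"] = tuple(d["epoch_window"])
        return cls(**d)

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class EpochSet:
    """Epoched multichannel data plus trial and channel metadata.

    ``data`` is trials x channels x time; ``trial_meta`` rows align with the
    first axis of ``data``; ``channels`` maps each channel to its hemisphere
    cluster ('left', 'right' or 'other'); ``times`` is in ms at 1 ms step.
    """

    data: np.ndarray
    trial_meta: pd.DataFrame
    channels: pd.DataFrame
    times: np.ndarray

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("trial_meta rows must match data trials")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel table must match data channels")
        if len(self.times) != self.data.shape[2]:
            raise ValueError("time axis must match data samples")
        if not set(self.channels["cluster"]).issubset({"left", "right", "other"}):
            raise ValueError("cluster labels must be left/right/other")

    @property
    def participants(self) -> np.ndarray:
        return np.unique(self.trial_meta["participant"].to_numpy())

    def for_participant(self, participant: int) -> "EpochSet":
        mask = (self.trial_meta["participant"] == participant).to_numpy()
        return EpochSet(
            self.data[mask],
            self.trial_meta.loc[mask].reset_index(drop=True),
            self.channels,
            self.times,
        )

    def channel_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.channels["name"])}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"channels not present in EpochSet: {missing}")
        return np.array([lookup[n] for n in names])


def _participant_rng(config: SimulationConfig, participant: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage, participant]))


def _sequence_presentations(stimuli: StimulusSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-sequence presentation schedule for one hemifield side.

    Images appear 4x per sequence (2 per hemifield in single sequences, 4 per
    side in dual sequences); words appear 8x (4 / side, respectively) — the
    word count is doubled because each word has half as many variants as each
    object has exemplars, and the analysis stage later subsamples words back
    to the image count.
    """
    images = np.repeat(stimuli.image_ids, 2)
    words = np.repeat(stimuli.word_ids, 4)
    return images, words


def generate_design(config: SimulationConfig, stimuli: StimulusSet | None = None) -> pd.DataFrame:
    """Generate the trial table for every participant and sequence.

    Single sequences present one stimulus per trial (images 2x per hemifield,
    words 4x per hemifield); dual sequences present one stimulus to each
    hemifield simultaneously (images 4x per side, words 8x per side, in random
    pairings).  Trials are 200 ms apart (100 ms on, 100 ms off) and ordered
    randomly within each sequence.
    """
    stimuli = stimuli or StimulusSet.default()
    images_half, words_half = _sequence_presentations(stimuli)
    side_list = np.concatenate([images_half, words_half])  # one hemifield's worth

    rows = []
    for participant in range(1, config.n_participants + 1):
        rng = _participant_rng(config, participant, _STAGE_DESIGN)
        for seq in range(config.n_single_sequences):
            lvf = np.concatenate([side_list, np.full(len(side_list), 0)])
            rvf = np.concatenate([np.full(len(side_list), 0), side_list])
            order = rng.permutation(len(lvf))
            lvf, rvf = lvf[order], rvf[order]
            for i, (l, r) in enumerate(zip(lvf, rvf)):
                rows.append((participant, "single", seq, i + 1,
                             l or pd.NA, r or pd.NA, i * 200))
        for seq in range(config.n_dual_sequences):
            lvf = np.concatenate([np.repeat(stimuli.image_ids, 4),
                                  np.repeat(stimuli.word_ids, 8)])
            rvf = lvf.copy()
            rng.shuffle(lvf)
            rng.shuffle(rvf)
            for i, (l, r) in enumerate(zip(lvf, rvf)):
                rows.append((participant, "dual", seq, i + 1, l, r, i * 200))

    table = pd.DataFrame(
        rows,
        columns=["participant", "condition", "sequence_index", "trial_index",
                 "lvf_stimulus", "rvf_stimulus", "onset_time"],
    )
    table["lvf_stimulus"] = table["lvf_stimulus"].astype("Int64")
    table["rvf_stimulus"] = table["rvf_stimulus"].astype("Int64")
    return table


def _orthonormal_map(rng: np.random.Generator, n_channels: int, dim: int) -> np.ndarray:
    """Random map from latent components to cluster channels.

    Rows (dim >= n_channels) or columns (dim < n_channels) are orthonormal so
    the projection neither inflates nor collapses pattern geometry.
    """
    if dim >= n_channels:
        g = rng.standard_normal((dim, dim))
        q, _ = np.linalg.qr(g)
        return q[:n_channels, :]
    g = rng.standard_normal((n_channels, n_channels))
    q, _ = np.linalg.qr(g)
    return q[:, :dim]


def _response_kernel(times: np.ndarray, onset: float, width: float) -> np.ndarray:
    """Raised-cosine (Hann) bump of the given width starting at ``onset``."""
    tau = times - onset
    k = np.where((tau >= 0) & (tau <= width),
                 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / max(width, 1))), 0.0)
    return k


def _latent_patterns(rng: np.random.Generator, stimuli: StimulusSet,
                     config: SimulationConfig) -> np.ndarray:
    """Stimulus latent patterns (n_stimuli, pattern_dim) with factor structure."""
    d = config.pattern_dim
    scale = 1.0 / math.sqrt(d)
    table = stimuli.table
    modalities = sorted(table["modality"].unique())
    concepts = sorted(table["concept"].unique())
    u_mod = {m: rng.standard_normal(d) * scale for m in modalities}
    v_con = {c: rng.standard_normal(d) * scale for c in concepts}
    eps = rng.standard_normal((len(table), d)) * scale
    pats = (
        math.sqrt(config.w_unique) * eps
        + math.sqrt(config.w_image) * np.stack([u_mod[m] for m in table["modality"]])
        + math.sqrt(config.w_concept) * np.stack([v_con[c] for c in table["concept"]])
    )
    return pats


def _channel_table(config: SimulationConfig) -> pd.DataFrame:
    k = config.n_channels_per_cluster
    names = list(LEFT_CLUSTER_CHANNELS[:k]) + list(RIGHT_CLUSTER_CHANNELS[:k]) + list(OTHER_CHANNELS)
    clusters = ["left"] * k + ["right"] * k + ["other"] * len(OTHER_CHANNELS)
    return pd.DataFrame({"name": names, "cluster": clusters})


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], a: float) -> np.ndarray:
    """Unit-marginal-variance AR(1) noise along the last axis."""
    burn = 0 if a == 0 else min(2000, int(np.ceil(10.0 / (1.0 - a))))
    white = rng.standard_normal(shape[:-1] + (shape[-1] + burn,))
    x = lfilter([1.0], [1.0, -a], white, axis=-1)[..., burn:]
    return x * math.sqrt(1.0 - a * a)


def generate_epochs(
    config: SimulationConfig,
    trials: pd.DataFrame,
    stimuli: StimulusSet | None = None,
) -> EpochSet:
    """Render EEG-like epochs for the given trial table.

    The contralateral cluster carries each presented stimulus's latent pattern
    under a raised-cosine bump at ``contra_onset``; the ipsilateral cluster a
    rank-reduced (``retention``), attenuated (``ipsi_gain``) copy delayed by
    ``transfer_delay``.  Dual-trial signal after ``interference_onset`` is
    scaled by ``interference_attenuation``.  AR(1) noise is added at the
    configured SNR (RMS signal / RMS noise over cluster channels, 0–500 ms);
    ``snr=0`` produces pure noise.  Fully reproducible from the config seed.
    """
    stimuli = stimuli or StimulusSet.default()
    channels = _channel_table(config)
    lo, hi = config.epoch_window
    times = np.arange(lo, hi + 1)
    n_ch = len(channels)
    k = config.n_channels_per_cluster
    left_idx = np.arange(0, k)
    right_idx = np.arange(k, 2 * k)
    cluster_idx = {"left": left_idx, "right": right_idx}
    signal_ch = np.concatenate([left_idx, right_idx])
    snr_window = (times >= 0) & (times <= 500)

    n_keep = int(math.ceil(config.retention * config.pattern_dim))
    kern_contra = _response_kernel(times, config.contra_onset, config.kernel_width)
    kern_ipsi = _response_kernel(times, config.contra_onset + config.transfer_delay,
                                 config.kernel_width)
    interference = times >= config.interference_onset

    parts = []
    metas = []
    for participant in np.unique(trials["participant"]):
        rng = _participant_rng(config, int(participant), _STAGE_EPOCHS)
        pats = _latent_patterns(rng, stimuli, config)
        maps = {h: _orthonormal_map(rng, k, config.pattern_dim) for h in ("left", "right")}

        # Per (stimulus, hemifield) channel x time signal templates.
        templates = {}
        for s_row, s_id in enumerate(stimuli.ids):
            pat = pats[s_row]
            pat_kept = pat.copy()
            pat_kept[n_keep:] = 0.0
            for hemifield, contra in (("LVF", "right"), ("RVF", "left")):
                ipsi = "left" if contra == "right" else "right"
                tpl = np.zeros((n_ch, len(times)))
                tpl[cluster_idx[contra]] = np.outer(maps[contra] @ pat, kern_contra)
                tpl[cluster_idx[ipsi]] = config.ipsi_gain * np.outer(
                    maps[ipsi] @ pat_kept, kern_ipsi)
                templates[(s_id, hemifield)] = tpl

        meta = trials.loc[trials["participant"] == participant].reset_index(drop=True)
        sig = np.zeros((len(meta), n_ch, len(times)))
        lvf = meta["lvf_stimulus"].to_numpy(dtype=object)
        rvf = meta["rvf_stimulus"].to_numpy(dtype=object)
        is_dual = (meta["condition"] == "dual").to_numpy()
        for i in range(len(meta)):
            if lvf[i] is not pd.NA and not pd.isna(lvf[i]):
                sig[i] += templates[(int(lvf[i]), "LVF")]
            if rvf[i] is not pd.NA and not pd.isna(rvf[i]):
                sig[i] += templates[(int(rvf[i]), "RVF")]
        if is_dual.any():
            sig[np.ix_(is_dual, np.arange(n_ch), interference)] *= config.interference_attenuation

        noise = _ar1_noise(rng, sig.shape, config.noise_autocorr)
        if config.snr == 0:
            data = noise
        else:
            rms_signal = math.sqrt(float(np.mean(
                sig[:, signal_ch][:, :, snr_window] ** 2)))
            sigma = rms_signal / config.snr
            data = sig + sigma * noise
        parts.append(data.astype(np.float32))
        metas.append(meta)

    return EpochSet(
        np.concatenate(parts, axis=0),
        pd.concat(metas, ignore_index=True),
        channels,
        times,
    )


def generate_triplet_responses(
    rdms: Sequence[np.ndarray],
    weights: Sequence[float],
    n_participants: int,
    n_trials: int = 400,
    decision_noise: float = 0.1,
    seed: int = 0,
    task: str = "image",
) -> pd.DataFrame:
    """Simulate triplet odd-one-out judgments under a Luce choice rule.

    The latent dissimilarity is ``D = Σ w_k RDM_k``.  On each trial three
    distinct stimuli are drawn uniformly; the probability of choosing stimulus
    i as the odd one out is a softmax (temperature ``decision_noise``) over
    each stimulus's summed dissimilarity to the other two.  ``decision_noise
    -> 0`` recovers the deterministic argmax (ties broken uniformly).
    """
    if len(rdms) != len(weights):
        raise ValueError("rdms and weights must have equal length")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be nonnegative")
    mats = [np.asarray(getattr(r, "values", r), dtype=float) for r in rdms]
    n_stim = mats[0].shape[0]
    if n_stim < 3:
        raise ValueError("need at least 3 stimuli for a triplet task")
    D = sum(w * m for w, m in zip(weights, mats))
    np.fill_diagonal(D, 0.0)

    rows = []
    letters = np.array(["a", "b", "c"])
    for participant in range(1, n_participants + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, _STAGE_TRIPLETS, participant]))
        for trial in range(1, n_trials + 1):
            trip = rng.choice(n_stim, size=3, replace=False)
            i, j, m = trip
            scores = np.array([D[i, j] + D[i, m], D[j, i] + D[j, m], D[m, i] + D[m, j]])
            if decision_noise <= 0:
                best = scores == scores.max()
                probs = best / best.sum()
            else:
                z = (scores - scores.max()) / decision_noise
                e = np.exp(z)
                probs = e / e.sum()
            choice = rng.choice(3, p=probs)
            rows.append((participant, trial, trip[0] + 1, trip[1] + 1, trip[2] + 1,
                         letters[choice], task))
    return pd.DataFrame(
        rows, columns=["participant", "trial", "stim_a", "stim_b", "stim_c", "chosen", "task"]
    )
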
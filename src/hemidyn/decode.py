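"""Time-resolved pairwise linear-discriminant decoding within electrode clusters.

For every unordered pair of stimuli and every 1-ms time point, a regularized
linear discriminant (pooled within-class covariance with Ledoit–Wolf
shrinkage toward the scaled identity) is trained on channel patterns from the
training folds and tested on the held-out fold; accuracy pooled over folds
fills one cell of the stimulus x stimulus neural RDM at that time point.
Folds contain independent trial sequences (fold = sequence rank mod n_folds),
so no sequence contributes to both training and test data.

The inner loop is vectorized across time: class means, shrunk covariances and
discriminant weights for all time points of one pair/fold are computed with
batched linear algebra, which is what makes the 630-pair x 901-time-point
problem tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synth import EpochSet, LEFT_CLUSTER_CHANNELS, RIGHT_CLUSTER_CHANNELS, StimulusSet

__all__ = [
    "ElectrodeCluster",
    "LEFT_CLUSTER",
    "RIGHT_CLUSTER",
    "NeuralRDMSeries",
    "AccuracyTimecourse",
    "stimulus_pairs",
    "n_pairwise_contrasts",
    "balance_word_trials",
    "pairwise_decode",
    "mean_accuracy",
    "collapse_contra_ipsi",
]


@dataclass(frozen=True)
class ElectrodeCluster:
    name: str
    channels: tuple[str, ...]


LEFT_CLUSTER = ElectrodeCluster("left", LEFT_CLUSTER_CHANNELS)
RIGHT_CLUSTER = ElectrodeCluster("right", RIGHT_CLUSTER_CHANNELS)


def stimulus_pairs(stimulus_ids: Sequence[int]) -> list[tuple[int, int]]:
    """All unordered stimulus pairs (630 for the full 36-stimulus set)."""
    return list(combinations(sorted(stimulus_ids), 2))


def n_pairwise_contrasts(n_stimuli: int) -> int:
    return n_stimuli * (n_stimuli - 1) // 2


@dataclass
class NeuralRDMSeries:
    """Stimulus x stimulus x time stack of pairwise decoding accuracies.

    Symmetric in the first two axes; the diagonal is undefined (NaN).
    ``sequences`` records which trial sequences contributed, which lets
    split-half analyses assert that correlated RDMs share no trials.
    """

    values: np.ndarray
    stimulus_ids: np.ndarray
    times: np.ndarray
    condition: str
    hemifield: str
    hemisphere: str
    split: str = "all"
    participant: int | None = None
    sequences: tuple[int, ...] = ()

    def __post_init__(self):
        s = len(self.stimulus_ids)
        if self.values.shape[:2] != (s, s) or self.values.shape[2] != len(self.times):
            raise ValueError("values must be n_stimuli x n_stimuli x n_times")

    @property
    def n_pairs(self) -> int:
        return n_pairwise_contrasts(len(self.stimulus_ids))

    def pair_vectors(self) -> np.ndarray:
        """Lower-triangle cells as an (n_pairs, n_times) matrix (fixed i<j order)."""
        iu = np.triu_indices(len(self.stimulus_ids), k=1)
        return self.values[iu]

    def mean_over_pairs(self) -> np.ndarray:
        return np.nanmean(self.pair_vectors(), axis=0)


@dataclass
class AccuracyTimecourse:
    values: np.ndarray
    times: np.ndarray
    labels: dict = field(default_factory=dict)


def _image_word_ids(trials: pd.DataFrame, stimuli: StimulusSet) -> tuple[set, set]:
    return set(stimuli.image_ids.tolist()), set(stimuli.word_ids.tolist())


def balance_word_trials(
    trials: pd.DataFrame, stimuli: StimulusSet, seed: int = 0
) -> pd.DataFrame:
    """Subsample word presentations to the per-image repeat count.

    Words are presented twice as often as images (a typeface doubling in the
    design); per condition and hemifield, each word stimulus is subsampled
    without replacement to exactly the image repeat count (48 in the full
    design), stratified over sequences as evenly as possible.  Because a dual
    trial carries one presentation per hemifield, retention is marked with
    boolean ``use_lvf``/``use_rvf`` columns rather than by dropping rows;
    image presentations are always retained.  Subsampling is performed
    independently within every participant's data.
    """
    rng = np.random.default_rng(seed)
    image_ids, word_ids = _image_word_ids(trials, stimuli)
    out = trials.copy()
    for side, col in (("LVF", "lvf_stimulus"), ("RVF", "rvf_stimulus")):
        out[f"use_{side.lower()}"] = out[col].notna()

    groups = [(p, c, side, col)
              for p in out["participant"].unique()
              for c in out["condition"].unique()
              for side, col in (("LVF", "lvf_stimulus"), ("RVF", "rvf_stimulus"))]
    for participant, condition, side, col in groups:
        present = ((out["participant"] == participant)
                   & (out["condition"] == condition) & out[col].notna())
        counts = out.loc[present, col].value_counts()
        img_counts = {int(counts.get(s, 0)) for s in image_ids}
        if not img_counts:
            raise ValueError("design contains no image stimuli to set the target count")
        if len(img_counts) != 1:
            raise ValueError(f"non-uniform image repeats in condition {condition}/{side}")
        target = img_counts.pop()
        for word in sorted(word_ids):
            rows = out.index[present & (out[col] == word)]
            if len(rows) < target:
                raise ValueError(
                    f"word stimulus {word} has only {len(rows)} repeats in "
                    f"condition {condition}/{side}; need {target}")
            if len(rows) == target:
                continue
            keep = _stratified_subsample(out.loc[rows, "sequence_index"].to_numpy(),
                                         rows.to_numpy(), target, rng)
            drop = np.setdiff1d(rows.to_numpy(), keep)
            out.loc[drop, f"use_{side.lower()}"] = False
    return out


def _stratified_subsample(strata: np.ndarray, rows: np.ndarray, target: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Pick ``target`` rows spread as evenly as possible over strata."""
    uniq = np.unique(strata)
    base, extra = divmod(target, len(uniq))
    bonus = set(rng.choice(uniq, size=extra, replace=False).tolist()) if extra else set()
    keep = []
    for u in uniq:
        pool = rows[strata == u]
        quota = base + (1 if u in bonus else 0)
        quota = min(quota, len(pool))
        keep.append(rng.choice(pool, size=quota, replace=False))
    keep = np.concatenate(keep)
    # top up if some strata were short
    if len(keep) < target:
        remaining = np.setdiff1d(rows, keep)
        keep = np.concatenate([keep, rng.choice(remaining, size=target - len(keep),
                                                replace=False)])
    return keep


def _ledoit_wolf_covariance(xc: np.ndarray, n: int) -> np.ndarray:
    """Shrunk pooled covariance per time point.

    ``xc``: centered training data (n, channels, T).  Returns (T, C, C)
    covariance matrices shrunk toward mu*I with the closed-form Ledoit–Wolf
    intensity computed independently at every time point.
    """
    c = xc.shape[1]
    s = np.einsum("ict,jct->tij", xc.transpose(1, 0, 2), xc.transpose(1, 0, 2))
    # note: einsum above builds S[t] = sum_i x_i x_i^T; divide by n
    s /= n
    mu = np.trace(s, axis1=1, axis2=2) / c
    norm2 = np.einsum("tij,tij->t", s, s)
    d2 = norm2 - c * mu**2  # ||S - mu I||_F^2
    quart = np.sum(np.sum(xc**2, axis=1) ** 2, axis=0)  # sum_i ||x_i||^4 per time
    b2 = (quart / n - norm2) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(d2 > 0, np.clip(b2 / d2, 0.0, 1.0), 1.0)
    eye = np.eye(c)
    return (1.0 - lam)[:, None, None] * s + (lam * mu)[:, None, None] * eye


def _pooled_covariance(xc: np.ndarray, n: int, shrinkage) -> np.ndarray:
    c = xc.shape[1]
    if shrinkage in ("ledoit-wolf", "lw"):
        return _ledoit_wolf_covariance(xc, n)
    s = np.einsum("ict,jct->tij", xc.transpose(1, 0, 2), xc.transpose(1, 0, 2)) / n
    if shrinkage is None or shrinkage == 0:
        return s
    lam = float(shrinkage)
    mu = np.trace(s, axis1=1, axis2=2) / c
    return (1.0 - lam) * s + (lam * mu)[:, None, None] * np.eye(c)


def _select_presentations(meta: pd.DataFrame, condition: str, hemifield: str) -> pd.DataFrame:
    col = "lvf_stimulus" if hemifield == "LVF" else "rvf_stimulus"
    use_col = f"use_{hemifield.lower()}"
    mask = (meta["condition"] == condition) & meta[col].notna()
    if use_col in meta.columns:
        mask &= meta[use_col].astype(bool)
    sel = meta.loc[mask, ["sequence_index", col]].copy()
    sel.columns = ["sequence_index", "stimulus"]
    sel["stimulus"] = sel["stimulus"].astype(int)
    sel["row"] = np.nonzero(mask.to_numpy())[0]
    return sel


def pairwise_decode(
    epochs: EpochSet,
    cluster: ElectrodeCluster,
    condition: str,
    hemifield: str,
    n_folds: int = 12,
    split: str = "all",
    shrinkage="ledoit-wolf",
) -> NeuralRDMSeries:
    """Cross-validated pairwise decoding of all stimulus pairs over time.

    Parameters
    ----------
    split
        'all' uses every sequence of the condition; 'odd'/'even' restrict to
        sequences of that parity (0-based ``sequence_index``), halving the
        fold count a split-half analysis should pass accordingly.
    shrinkage
        'ledoit-wolf' (default), a fixed intensity in [0, 1], or None for the
        plain pooled covariance (no regularization).

    Accuracy at a time point is the proportion of correctly classified
    held-out trials pooled over folds; decision-boundary ties go to the
    smaller stimulus id.
    """
    participants = epochs.participants
    if len(participants) != 1:
        raise ValueError("pairwise_decode expects a single participant's epochs; "
                         "use EpochSet.for_participant")
    ch_idx = epochs.channel_indices(cluster.channels)
    sel = _select_presentations(epochs.trial_meta, condition, hemifield)
    if split in ("odd", "even"):
        parity = 1 if split == "odd" else 0
        sel = sel[sel["sequence_index"] % 2 == parity]
    elif split != "all":
        raise ValueError("split must be 'all', 'odd' or 'even'")
    if sel.empty:
        raise ValueError(f"no presentations for condition={condition}, hemifield={hemifield}")

    seqs = np.sort(sel["sequence_index"].unique())
    if len(seqs) % n_folds != 0:
        raise ValueError(
            f"n_folds={n_folds} does not divide the {len(seqs)} sequences of split '{split}'")
    fold_of_seq = {s: i % n_folds for i, s in enumerate(seqs)}
    folds = sel["sequence_index"].map(fold_of_seq).to_numpy()

    stim_ids = np.sort(sel["stimulus"].unique())
    stim_pos = {s: i for i, s in enumerate(stim_ids)}
    labels = sel["stimulus"].to_numpy()
    rows = sel["row"].to_numpy()

    # index trials per (stimulus, fold); every stimulus must appear in every fold
    trial_idx: dict[tuple[int, int], np.ndarray] = {}
    for s in stim_ids:
        for f in range(n_folds):
            idx = rows[(labels == s) & (folds == f)]
            if len(idx) == 0:
                raise ValueError(f"stimulus {s} absent from fold {f}")
            trial_idx[(s, f)] = idx

    x = epochs.data[:, ch_idx, :].astype(np.float64)
    n_stim, n_t = len(stim_ids), x.shape[2]
    acc = np.full((n_stim, n_stim, n_t), np.nan, dtype=np.float32)

    for a, b in combinations(stim_ids, 2):
        correct = np.zeros(n_t)
        total = 0
        for f in range(n_folds):
            tr_a = np.concatenate([trial_idx[(a, g)] for g in range(n_folds) if g != f])
            tr_b = np.concatenate([trial_idx[(b, g)] for g in range(n_folds) if g != f])
            te_a, te_b = trial_idx[(a, f)], trial_idx[(b, f)]
            xa, xb = x[tr_a], x[tr_b]
            mu_a, mu_b = xa.mean(axis=0), xb.mean(axis=0)  # (C, T)
            xc = np.concatenate([xa - mu_a, xb - mu_b], axis=0)
            cov = _pooled_covariance(xc, xc.shape[0], shrinkage)  # (T, C, C)
            diff = (mu_a - mu_b).T[..., None]  # (T, C, 1)
            w = np.linalg.solve(cov, diff)[..., 0]  # (T, C)
            thresh = np.einsum("tc,ct->t", w, (mu_a + mu_b) / 2.0)
            score_a = np.einsum("ict,tc->it", x[te_a], w) - thresh
            score_b = np.einsum("ict,tc->it", x[te_b], w) - thresh
            # ties (score == 0) go to the smaller stimulus id, i.e. class a
            correct += (score_a >= 0).sum(axis=0) + (score_b < 0).sum(axis=0)
            total += len(te_a) + len(te_b)
        pa, pb = stim_pos[a], stim_pos[b]
        acc[pa, pb] = acc[pb, pa] = correct / total

    return NeuralRDMSeries(
        values=acc,
        stimulus_ids=stim_ids,
        times=epochs.times,
        condition=condition,
        hemifield=hemifield,
        hemisphere=cluster.name,
        split=split,
        participant=int(participants[0]),
        sequences=tuple(int(s) for s in seqs),
    )


def mean_accuracy(rdm: NeuralRDMSeries) -> AccuracyTimecourse:
    """Mean pairwise decoding accuracy over the unique stimulus pairs."""
    return AccuracyTimecourse(
        values=rdm.mean_over_pairs(),
        times=rdm.times,
        labels={"condition": rdm.condition, "hemifield": rdm.hemifield,
                "hemisphere": rdm.hemisphere, "split": rdm.split,
                "participant": rdm.participant},
    )


_CONTRA_KEYS = (("left", "RVF"), ("right", "LVF"))
_IPSI_KEYS = (("left", "LVF"), ("right", "RVF"))


def collapse_contra_ipsi(results: Mapping[tuple[str, str], object]) -> dict[str, np.ndarray]:
    """Average hemisphere x hemifield results into contralateral / ipsilateral.

    ``results`` maps (hemisphere, hemifield) to an AccuracyTimecourse,
    NeuralRDMSeries or plain array; averaging is element-wise.  Contralateral
    pools left-hemisphere/RVF with right-hemisphere/LVF; ipsilateral the
    complement.
    """
    def values(obj):
        if isinstance(obj, (AccuracyTimecourse, NeuralRDMSeries)):
            return np.asarray(obj.values, dtype=float)
        return np.asarray(obj, dtype=float)

    missing = [k for k in _CONTRA_KEYS + _IPSI_KEYS if k not in results]
    if missing:
        raise KeyError(f"missing hemisphere x hemifield combinations: {missing}")
    return {
        "contralateral": np.mean([values(results[k]) for k in _CONTRA_KEYS], axis=0),
        "ipsilateral": np.mean([values(results[k]) for k in _IPSI_KEYS], axis=0),
    }
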
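"""File formats: native epoch container, RDM stacks, and EEG-format import.

The native epoch container is a compressed array file (``<stem>.npz``) plus a
JSON sidecar for channel/cluster metadata and a CSV trial table — binary
payload, diff-able metadata.  Epoched data recorded in standard EEG formats
(BrainVision ``.vhdr`` triplets, EEGLAB ``.set``) can be imported through MNE
when it is installed, with trial metadata supplied by a ``<stem>.trials.csv``
sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decode import LEFT_CLUSTER, RIGHT_CLUSTER, NeuralRDMSeries
from .synth import EpochSet

__all__ = [
    "save_epochs",
    "load_epochs",
    "import_epochs",
    "save_rdm_series",
    "load_rdm_series",
    "rdm_series_to_frame",
]

_TRIAL_INT_COLS = ("participant", "sequence_index", "trial_index", "onset_time")


def save_epochs(epochs: EpochSet, stem: str | Path) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(stem.with_suffix(".npz"), data=epochs.data, times=epochs.times)
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump({"channels": epochs.channels.to_dict(orient="records")}, fh, indent=2)
    epochs.trial_meta.to_csv(stem.with_suffix(".trials.csv"), index=False)


def load_epochs(stem: str | Path) -> EpochSet:
    stem = Path(stem)
    with np.load(stem.with_suffix(".npz")) as z:
        data, times = z["data"], z["times"]
    with open(stem.with_suffix(".json")) as fh:
        channels = pd.DataFrame(json.load(fh)["channels"])
    meta = pd.read_csv(stem.with_suffix(".trials.csv"))
    for col in ("lvf_stimulus", "rvf_stimulus"):
        if col in meta.columns:
            meta[col] = meta[col].astype("Int64")
    return EpochSet(data, meta, channels, times)


def _cluster_table(ch_names: list[str]) -> pd.DataFrame:
    missing = [c for c in LEFT_CLUSTER.channels + RIGHT_CLUSTER.channels
               if c not in ch_names]
    if missing:
        raise ValueError(f"imported data lacks cluster channels: {missing}")
    cluster = ["left" if c in LEFT_CLUSTER.channels
               else "right" if c in RIGHT_CLUSTER.channels
               else "other" for c in ch_names]
    return pd.DataFrame({"name": ch_names, "cluster": cluster})


def import_epochs(path: str | Path, format: str = "native") -> EpochSet:
    """Load epoched data from the native container or a standard EEG format.

    Non-native formats require MNE and a ``<stem>.trials.csv`` sidecar with
    the trial table (one row per epoch, in epoch order).  The time axis is
    asserted/resampled to 1 ms resolution and channels are mapped to the
    left/right occipito-temporal clusters by their 10-20 names.
    """
    path = Path(path)
    if format == "native":
        return load_epochs(path.with_suffix(""))
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError("importing EEG formats requires the 'mne' package") from exc

    stem = path.with_suffix("")
    meta_path = stem.parent / (stem.name + ".trials.csv")
    if not meta_path.exists():
        raise FileNotFoundError(f"trial-table sidecar not found: {meta_path}")
    meta = pd.read_csv(meta_path)

    if format == "eeglab_set":
        ep = mne.read_epochs_eeglab(path, verbose="error")
    elif format == "brainvision":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        if "epoch_sample" not in meta.columns:
            raise ValueError("BrainVision import needs an 'epoch_sample' column "
                             "giving each epoch's onset sample")
        events = np.column_stack([
            meta["epoch_sample"].to_numpy(int),
            np.zeros(len(meta), dtype=int),
            np.ones(len(meta), dtype=int),
        ])
        ep = mne.Epochs(raw, events, tmin=-0.1, tmax=0.8, baseline=None,
                        preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported format: {format}")

    if abs(ep.info["sfreq"] - 1000.0) > 1e-6:
        ep = ep.resample(1000.0)
    data = ep.get_data(copy=True).astype(np.float32)
    times = np.round(ep.times * 1000.0).astype(int)
    channels = _cluster_table(list(ep.ch_names))
    meta = meta.iloc[: data.shape[0]].reset_index(drop=True)
    for col in ("lvf_stimulus", "rvf_stimulus"):
        if col in meta.columns:
            meta[col] = meta[col].astype("Int64")
    return EpochSet(data, meta, channels, np.asarray(times))


def save_rdm_series(rdm: NeuralRDMSeries, stem: str | Path) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(stem.with_suffix(".npz"), values=rdm.values,
                        stimulus_ids=rdm.stimulus_ids, times=rdm.times)
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump({"condition": rdm.condition, "hemifield": rdm.hemifield,
                   "hemisphere": rdm.hemisphere, "split": rdm.split,
                   "participant": rdm.participant,
                   "sequences": list(rdm.sequences)}, fh, indent=2)


def load_rdm_series(stem: str | Path) -> NeuralRDMSeries:
    stem = Path(stem)
    with np.load(stem.with_suffix(".npz")) as z:
        values, ids, times = z["values"], z["stimulus_ids"], z["times"]
    with open(stem.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return NeuralRDMSeries(values=values, stimulus_ids=ids, times=times,
                           condition=meta["condition"], hemifield=meta["hemifield"],
                           hemisphere=meta["hemisphere"], split=meta["split"],
                           participant=meta["participant"],
                           sequences=tuple(meta["sequences"]))


def rdm_series_to_frame(rdm: NeuralRDMSeries) -> pd.DataFrame:
    """Long-format table: one row per stimulus pair per time point."""
    ids = rdm.stimulus_ids
    iu = np.triu_indices(len(ids), k=1)
    cells = rdm.pair_vectors()
    n_pairs, n_t = cells.shape
    return pd.DataFrame({
        "participant": rdm.participant,
        "condition": rdm.condition,
        "hemisphere": rdm.hemisphere,
        "hemifield": rdm.hemifield,
        "split": rdm.split,
        "time_ms": np.tile(rdm.times, n_pairs),
        "stim_i": np.repeat(ids[iu[0]], n_t),
        "stim_j": np.repeat(ids[iu[1]], n_t),
        "accuracy": cells.ravel(),
    })
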
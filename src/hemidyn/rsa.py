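"""Interhemispheric representational similarity over time.

Compares the representational geometry of the two hemispheres by Spearman-
correlating their neural RDMs for every pair of time points (temporal
generalization), always across split halves (odd vs even trial sequences) so
that correlated noise cannot inflate the correlations.  The off-diagonal
structure of the time x time surface yields a transfer-delay profile whose
argmax estimates the interhemispheric delay; a directional Bayes-factor test
on profile(+d) - profile(-d) quantifies the "contralateral leads" asymmetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bayes import BFSpec, jzs_interval_bf
from .decode import NeuralRDMSeries, collapse_contra_ipsi

__all__ = [
    "TimeGenMatrix",
    "DelayProfile",
    "crosscorrelate_timegen",
    "delay_profile",
    "asymmetry_test",
    "consistency_within_across",
    "spearman_columns",
]


@dataclass
class TimeGenMatrix:
    """Time x time rank-correlation surface.

    Rows index the time axis of the first (conventionally contralateral)
    series, columns that of the second (ipsilateral) series.  Cells where a
    time point's RDM had zero variance are NaN and are excluded from any
    downstream averaging.
    """

    values: np.ndarray
    times_a: np.ndarray
    times_b: np.ndarray
    condition: str = ""
    labels: dict = field(default_factory=dict)


@dataclass
class DelayProfile:
    """Mean correlation per contralateral->ipsilateral delay.

    Positive delay = contralateral leads (the ipsilateral RDM at t + d is
    compared with the contralateral RDM at t).
    """

    delays: np.ndarray
    values: np.ndarray
    labels: dict = field(default_factory=dict)

    @property
    def argmax_delay(self) -> int:
        return int(self.delays[np.nanargmax(self.values)])


def _rank_z(cells: np.ndarray) -> np.ndarray:
    """Column-wise average-fractional ranks, z-scored; zero-variance -> NaN."""
    r = rankdata(cells, axis=0)
    r = r - r.mean(axis=0, keepdims=True)
    sd = r.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, r / sd, np.nan)
    return z


def spearman_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman correlation of corresponding columns of two (n, T) matrices."""
    za, zb = _rank_z(a), _rank_z(b)
    return np.mean(za * zb, axis=0)


def _check_split_purity(a: NeuralRDMSeries, b: NeuralRDMSeries) -> None:
    shared = set(a.sequences) & set(b.sequences)
    if a.sequences and b.sequences and shared:
        raise ValueError(f"split-half RDMs share trial sequences {sorted(shared)}; "
                         "correlations must cross independent splits")


def _surface(a: NeuralRDMSeries, b: NeuralRDMSeries) -> np.ndarray:
    if not np.array_equal(a.stimulus_ids, b.stimulus_ids):
        raise ValueError("RDM series must share the stimulus set")
    _check_split_purity(a, b)
    za = _rank_z(a.pair_vectors())
    zb = _rank_z(b.pair_vectors())
    n = za.shape[0]
    # NaN columns (zero variance) propagate through the product
    return (np.nan_to_num(za).T @ np.nan_to_num(zb)) / n + _nan_mask(za, zb)


def _nan_mask(za: np.ndarray, zb: np.ndarray) -> np.ndarray:
    bad_a = np.isnan(za).any(axis=0)
    bad_b = np.isnan(zb).any(axis=0)
    mask = np.zeros((za.shape[1], zb.shape[1]))
    mask[bad_a, :] = np.nan
    mask[:, bad_b] = np.nan
    return mask


def crosscorrelate_timegen(
    a_odd: NeuralRDMSeries,
    b_even: NeuralRDMSeries,
    a_even: NeuralRDMSeries | None = None,
    b_odd: NeuralRDMSeries | None = None,
) -> TimeGenMatrix:
    """Split-half time x time Spearman correlation between two RDM series.

    With all four split RDMs supplied, the surface is the mean of the two
    cross pairings (odd-A x even-B and even-A x odd-B), which is symmetric in
    the split assignment and lower variance than either pairing alone.
    """
    surf = _surface(a_odd, b_even)
    if a_even is not None and b_odd is not None:
        stacked = np.stack([surf, _surface(a_even, b_odd)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells stay NaN
            surf = np.nanmean(stacked, axis=0)
    return TimeGenMatrix(
        values=surf,
        times_a=a_odd.times,
        times_b=b_even.times,
        condition=a_odd.condition,
        labels={"a": a_odd.hemisphere, "b": b_even.hemisphere,
                "hemifield": a_odd.hemifield, "participant": a_odd.participant},
    )


def delay_profile(
    tg: TimeGenMatrix,
    delay_range: tuple[int, int] = (-100, 100),
    window: tuple[int, int] = (0, 500),
) -> DelayProfile:
    """Mean off-diagonal correlation per delay.

    For each delay d, averages ``values[t, t+d]`` over contralateral times t
    inside ``window`` (cells falling outside either axis, or NaN, are
    skipped).  Positive d = column (ipsilateral) time lags the row
    (contralateral) time.
    """
    delays = np.arange(delay_range[0], delay_range[1] + 1)
    ta = np.asarray(tg.times_a)
    tb = np.asarray(tg.times_b)
    t_in = np.nonzero((ta >= window[0]) & (ta <= window[1]))[0]
    if len(t_in) == 0:
        raise ValueError("averaging window contains no time points")
    pos_b = {t: i for i, t in enumerate(tb)}
    out = np.full(len(delays), np.nan)
    for i, d in enumerate(delays):
        rows, cols = [], []
        for r in t_in:
            j = pos_b.get(ta[r] + d)
            if j is not None:
                rows.append(r)
                cols.append(j)
        if rows:
            out[i] = np.nanmean(tg.values[rows, cols])
    if np.isnan(out).all():
        raise ValueError("no valid diagonal cells for any delay")
    return DelayProfile(delays=delays, values=out, labels=dict(tg.labels))


def asymmetry_test(
    profiles: np.ndarray,
    delays: np.ndarray,
    spec: BFSpec | None = None,
) -> pd.DataFrame:
    """Directional Bayes factors for profile(+d) > profile(-d) per |d|.

    ``profiles`` is participants x delays.  For every |d| >= 1 present with
    both signs, the paired per-participant difference is tested against zero
    with a directional interval-null JZS Bayes factor.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if profiles.shape[0] < 2:
        raise ValueError("asymmetry test requires at least 2 participants")
    spec = spec or BFSpec(direction="greater", mu0=0.0)
    pos = {int(d): i for i, d in enumerate(delays)}
    rows = []
    for d in sorted({abs(int(d)) for d in delays if d != 0}):
        if d in pos and -d in pos:
            diff = profiles[:, pos[d]] - profiles[:, pos[-d]]
            rows.append((d, jzs_interval_bf(diff, spec)))
    return pd.DataFrame(rows, columns=["abs_delay", "bf"])


def consistency_within_across(
    rdms: Mapping[tuple[str, str, str], NeuralRDMSeries],
) -> dict[str, np.ndarray]:
    """Within- vs across-hemisphere RDM consistency over time.

    ``rdms`` maps (hemisphere, hemifield, split) with split in {'odd','even'}
    to an RDM series.  Within-hemisphere consistency is the same-time
    Spearman correlation of a hemisphere's odd vs even RDMs (a reliability
    noise ceiling); across-hemisphere consistency is the diagonal of the
    split-half left-right surface.  Results are collapsed into contralateral
    / ipsilateral (within) and a single 'across' time course.
    """
    needed = [(h, f, s) for h in ("left", "right") for f in ("LVF", "RVF")
              for s in ("odd", "even")]
    missing = [k for k in needed if k not in rdms]
    if missing:
        raise KeyError(f"missing RDM splits: {missing}")

    within = {}
    for h in ("left", "right"):
        for f in ("LVF", "RVF"):
            a, b = rdms[(h, f, "odd")], rdms[(h, f, "even")]
            _check_split_purity(a, b)
            within[(h, f)] = spearman_columns(a.pair_vectors(), b.pair_vectors())
    collapsed = collapse_contra_ipsi(within)

    across = []
    for f in ("LVF", "RVF"):
        tg = crosscorrelate_timegen(rdms[("left", f, "odd")], rdms[("right", f, "even")],
                                    rdms[("left", f, "even")], rdms[("right", f, "odd")])
        across.append(np.diagonal(tg.values))
    return {
        "within_contra": collapsed["contralateral"],
        "within_ipsi": collapsed["ipsilateral"],
        "across": np.mean(across, axis=0),
    }
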
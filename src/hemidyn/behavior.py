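"""Behavioral similarity estimation from triplet odd-one-out judgments.

On each trial three stimuli are shown and the participant picks the odd one
out; the chosen stimulus is coded as dissimilar (1) from each of the other
two and the remaining pair as similar (0).  Pooled over all trials of all
participants, the mean code per stimulus pair forms a behavioral RDM.  Two
binary stimulus models — image/word membership and six-concept membership —
and Spearman/Steiger machinery relate behavioral RDMs to each other and to
neural RDM time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .decode import NeuralRDMSeries
from .synth import StimulusSet

__all__ = [
    "RDM",
    "CorrelationResult",
    "DependentCorrelationTest",
    "build_rdm_from_triplets",
    "build_model_rdms",
    "correlate_rdms",
    "compare_dependent_correlations",
    "neural_behavior_timecourse",
    "mds_embedding",
]


@dataclass
class RDM:
    """A symmetric stimulus x stimulus dissimilarity matrix.

    Behavioral RDM cells lie in [0, 1] (mean odd-one-out codes) and may be
    NaN for pairs never observed together; model RDMs are binary.
    ``pair_counts`` records, for behavioral RDMs, how many triplet trials
    contributed to each cell.
    """

    values: np.ndarray
    name: str = ""
    pair_counts: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RDM must be square")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ValueError("RDM must be symmetric")
        self.values = v

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    def pair_vector(self) -> np.ndarray:
        iu = np.triu_indices(self.n_stimuli, k=1)
        return self.values[iu]


@dataclass
class CorrelationResult:
    rho: float
    n_pairs: int
    p_value: float | None = None


@dataclass
class DependentCorrelationTest:
    z: float
    r1: float
    r2: float
    r12: float
    n: int


def build_rdm_from_triplets(responses: pd.DataFrame, n_stimuli: int | None = None) -> RDM:
    """Estimate a behavioral RDM from pooled triplet responses.

    Each trial contributes codes for its three stimulus pairs: 1 for the two
    pairs involving the chosen odd-one-out, 0 for the remaining pair.  Cell
    values are means over all trials (all participants pooled) containing the
    pair; never co-observed pairs are NaN.
    """
    stims = responses[["stim_a", "stim_b", "stim_c"]].to_numpy(dtype=int)
    if n_stimuli is None:
        n_stimuli = int(stims.max())
    chosen = responses["chosen"].map({"a": 0, "b": 1, "c": 2}).to_numpy()
    if np.isnan(chosen.astype(float)).any():
        raise ValueError("chosen must be one of 'a', 'b', 'c'")
    if (stims < 1).any() or (stims > n_stimuli).any():
        raise ValueError("stimulus ids out of range")
    if (np.diff(np.sort(stims, axis=1), axis=1) == 0).any():
        raise ValueError("triplet stimuli must be distinct")

    sums = np.zeros((n_stimuli, n_stimuli))
    counts = np.zeros((n_stimuli, n_stimuli), dtype=int)
    pair_slots = [(0, 1), (0, 2), (1, 2)]
    for (p, q) in pair_slots:
        i, j = stims[:, p] - 1, stims[:, q] - 1
        code = ((chosen == p) | (chosen == q)).astype(float)
        np.add.at(sums, (i, j), code)
        np.add.at(sums, (j, i), code)
        np.add.at(counts, (i, j), 1)
        np.add.at(counts, (j, i), 1)

    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(values, np.nan)
    task = responses["task"].iloc[0] if "task" in responses.columns else ""
    return RDM(values=values, name=str(task), pair_counts=counts)


def build_model_rdms(stimuli: StimulusSet) -> dict[str, RDM]:
    """Binary stimulus models: modality (image vs word) and shared concept."""
    t = stimuli.table
    modality = t["modality"].to_numpy()
    concept = t["concept"].to_numpy()
    image_model = (modality[:, None] != modality[None, :]).astype(float)
    concept_model = (concept[:, None] != concept[None, :]).astype(float)
    return {
        "image_model": RDM(values=image_model, name="image_model"),
        "concept_model": RDM(values=concept_model, name="concept_model"),
    }


def _pair_vec(rdm) -> np.ndarray:
    if isinstance(rdm, RDM):
        return rdm.pair_vector()
    if isinstance(rdm, NeuralRDMSeries):
        raise TypeError("use neural_behavior_timecourse for RDM time series")
    v = np.asarray(rdm, dtype=float)
    if v.ndim == 2 and v.shape[0] == v.shape[1]:
        iu = np.triu_indices(v.shape[0], k=1)
        return v[iu]
    return v.ravel()


def correlate_rdms(a, b, n_permutations: int = 0, seed: int = 0) -> CorrelationResult:
    """Spearman correlation over pairwise-complete lower-triangle cells.

    A permutation p-value (random relabelings of one RDM's stimuli) is
    computed only when ``n_permutations`` > 0; no parametric p is reported
    because RDM cells are not independent observations.
    """
    va, vb = _pair_vec(a), _pair_vec(b)
    if va.shape != vb.shape:
        raise ValueError("RDMs must cover the same stimulus pairs")
    ok = np.isfinite(va) & np.isfinite(vb)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    rho = float(spearmanr(va[ok], vb[ok]).statistic)

    p = None
    if n_permutations > 0:
        mb = np.asarray(getattr(b, "values", b), dtype=float)
        if mb.ndim != 2:
            raise ValueError("permutation test needs a full square RDM for b")
        rng = np.random.default_rng(seed)
        n = mb.shape[0]
        iu = np.triu_indices(n, k=1)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            vp = mb[np.ix_(perm, perm)][iu]
            okp = np.isfinite(va) & np.isfinite(vp)
            r = spearmanr(va[okp], vp[okp]).statistic
            if abs(r) >= abs(rho):
                count += 1
        p = (1 + count) / (1 + n_permutations)
    return CorrelationResult(rho=rho, n_pairs=int(ok.sum()), p_value=p)


def compare_dependent_correlations(r1: float, r2: float, r12: float,
                                   n: int) -> DependentCorrelationTest:
    """Steiger's z for two dependent correlations sharing one variable.

    Tests r1 = corr(x, y1) against r2 = corr(x, y2) given r12 = corr(y1, y2),
    using Fisher-transformed correlations and the shared-variable covariance
    correction with the pooled estimate r̄ = (r1 + r2) / 2.
    """
    for r in (r1, r2, r12):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    z1 = np.arctanh(r1)
    z2 = np.arctanh(r2)
    rbar = (r1 + r2) / 2.0
    cov = (r12 * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2
           * (1.0 - 2.0 * rbar**2 - r12**2)) / (1.0 - rbar**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 - 2.0 * cov))
    return DependentCorrelationTest(z=float(z), r1=r1, r2=r2, r12=r12, n=n)


def neural_behavior_timecourse(neural: NeuralRDMSeries, behavior: RDM) -> CorrelationResult:
    """Spearman correlation of the neural RDM with a behavioral RDM per time point.

    Returns an object with ``rho`` as a time-course array; pairwise-complete
    cells (behavioral NaNs excluded) are used at every time point.
    """
    from .rsa import spearman_columns  # local import avoids a module cycle

    if behavior.n_stimuli != len(neural.stimulus_ids):
        raise ValueError("stimulus sets do not match")
    vb = behavior.pair_vector()
    cells = neural.pair_vectors()
    ok = np.isfinite(vb)
    rho = spearman_columns(cells[ok], np.repeat(vb[ok, None], cells.shape[1], axis=1))
    return CorrelationResult(rho=rho, n_pairs=int(ok.sum()))


def mds_embedding(rdm: RDM, n_dim: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric MDS embedding of an RDM, for plotting.

    Not part of the inferential pipeline; NaN cells are filled with the mean
    dissimilarity before double-centering.
    """
    d = np.array(rdm.values, dtype=float)
    np.fill_diagonal(d, 0.0)
    d[np.isnan(d)] = np.nanmean(d)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:n_dim]
    return v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
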
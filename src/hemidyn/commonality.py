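"""Commonality (variance-partitioning) analysis of neural RDMs.

OLS regression of the neural RDM cells on the image-task and concept-task
behavioral models, run as a full two-predictor model and as each
single-predictor model, partitions the explained variance into

    unique_image   = R²_full − R²_concept
    unique_concept = R²_full − R²_image
    common         = R²_image + R²_concept − R²_full

which sum exactly to R²_full.  Negative commonality (suppressor structure)
is mathematically possible and reported as-is.  Significance comes from a
permutation null that jointly permutes the stimulus labels (rows and columns)
of the neural RDM — permuting cells directly would break RDM geometry — with
one permutation set shared across time so the null preserves the temporal
dependence of the observed series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decode import NeuralRDMSeries

__all__ = [
    "VariancePartition",
    "PermutationNull",
    "variance_partition",
    "permutation_test",
]

_COMPONENTS = ("unique_image", "unique_concept", "common")


@dataclass
class VariancePartition:
    """R² values and their partition; entries are scalars or per-time arrays."""

    r2_full: np.ndarray
    r2_image: np.ndarray
    r2_concept: np.ndarray
    unique_image: np.ndarray
    unique_concept: np.ndarray
    common: np.ndarray


@dataclass
class PermutationNull:
    """Null distributions and p-values for each partition component.

    ``null`` maps component name to an (n_permutations, n_times) array; the
    add-one p-value convention makes the smallest attainable p equal to
    1/(n_permutations + 1); ``significant`` flags observations exceeding
    every permutation.
    """

    observed: VariancePartition
    null: dict[str, np.ndarray]
    p_values: dict[str, np.ndarray]
    significant: dict[str, np.ndarray]
    n_permutations: int
    seed: int


def _design_q(columns: list[np.ndarray]) -> np.ndarray:
    """Orthonormal basis (QR) of an intercept-plus-predictors design."""
    n = len(columns[0])
    x = np.column_stack([np.ones(n)] + columns)
    q, r = np.linalg.qr(x)
    if np.abs(np.diag(r)).min() < 1e-10 * np.abs(np.diag(r)).max():
        raise ValueError("collinear predictors: variance partition undefined")
    return q


def _r2(q: np.ndarray, y: np.ndarray, sst: np.ndarray, ybar: np.ndarray) -> np.ndarray:
    # SSE = ||y - Q Q^T y||^2; R^2 = 1 - SSE / SST (intercept included in Q)
    proj = q @ (q.T @ y)
    sse = np.sum((y - proj) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sst > 0, 1.0 - sse / sst, np.nan)


def variance_partition(neural_cells: np.ndarray, image_model: np.ndarray,
                       concept_model: np.ndarray) -> VariancePartition:
    """Partition neural RDM variance between two model predictors.

    ``neural_cells`` is a pair vector (n_pairs,) or stack (n_pairs, T);
    the model vectors align with the same fixed pair ordering.
    """
    y = np.asarray(neural_cells, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    img = np.asarray(image_model, dtype=float).ravel()
    con = np.asarray(concept_model, dtype=float).ravel()
    if len(img) != y.shape[0] or len(con) != y.shape[0]:
        raise ValueError("model vectors must align with neural cells")

    q_full = _design_q([img, con])
    q_img = _design_q([img])
    q_con = _design_q([con])
    ybar = y.mean(axis=0)
    sst = np.sum((y - ybar) ** 2, axis=0)
    r2_full = _r2(q_full, y, sst, ybar)
    r2_img = _r2(q_img, y, sst, ybar)
    r2_con = _r2(q_con, y, sst, ybar)

    def fin(a):
        return float(a[0]) if squeeze else a

    return VariancePartition(
        r2_full=fin(r2_full),
        r2_image=fin(r2_img),
        r2_concept=fin(r2_con),
        unique_image=fin(r2_full - r2_con),
        unique_concept=fin(r2_full - r2_img),
        common=fin(r2_img + r2_con - r2_full),
    )


def _condensed_index(n: int) -> np.ndarray:
    """Matrix mapping (i, j) to the index of the pair in the i<j cell vector."""
    idx = np.zeros((n, n), dtype=int)
    iu = np.triu_indices(n, k=1)
    idx[iu] = np.arange(len(iu[0]))
    idx = idx + idx.T
    return idx


def permutation_test(
    neural: NeuralRDMSeries | np.ndarray,
    image_model: np.ndarray,
    concept_model: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    per_time_permutations: bool = False,
) -> PermutationNull:
    """Stimulus-label permutation null for the variance partition.

    Each repetition draws one random permutation of the stimulus labels,
    reorders the neural RDM's rows and columns jointly, and recomputes the
    partition at every time point (the same permutation is applied to all
    time points unless ``per_time_permutations``).  p-values use the add-one
    convention; the ``significant`` flag marks observed values exceeding all
    permutations (p = 1/(n+1)).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if isinstance(neural, NeuralRDMSeries):
        cells = neural.pair_vectors()
        n_stim = len(neural.stimulus_ids)
    else:
        mat = np.asarray(neural, dtype=float)
        if mat.ndim == 2:
            mat = mat[:, :, None]
        n_stim = mat.shape[0]
        iu = np.triu_indices(n_stim, k=1)
        cells = mat[iu]
    img = np.asarray(getattr(image_model, "pair_vector", lambda: image_model)(), dtype=float).ravel()
    con = np.asarray(getattr(concept_model, "pair_vector", lambda: concept_model)(), dtype=float).ravel()

    observed = variance_partition(cells, img, con)
    obs = {k: np.atleast_1d(getattr(observed, k)) for k in _COMPONENTS}

    rng = np.random.default_rng(seed)
    sq = _condensed_index(n_stim)
    iu = np.triu_indices(n_stim, k=1)
    n_t = cells.shape[1]
    null = {k: np.empty((n_permutations, n_t)) for k in _COMPONENTS}
    for p in range(n_permutations):
        if per_time_permutations:
            y = np.empty_like(cells)
            for t in range(n_t):
                perm = rng.permutation(n_stim)
                y[:, t] = cells[sq[perm[:, None], perm[None, :]][iu], t]
        else:
            perm = rng.permutation(n_stim)
            gather = sq[perm[:, None], perm[None, :]][iu]
            y = cells[gather]
        part = variance_partition(y, img, con)
        for k in _COMPONENTS:
            null[k][p] = np.atleast_1d(getattr(part, k))

    p_values = {}
    significant = {}
    for k in _COMPONENTS:
        ge = (null[k] >= obs[k][None, :]).sum(axis=0)
        p_values[k] = (1.0 + ge) / (1.0 + n_permutations)
        significant[k] = obs[k] > null[k].max(axis=0)
    return PermutationNull(
        observed=observed,
        null=null,
        p_values=p_values,
        significant=significant,
        n_permutations=n_permutations,
        seed=seed,
    )
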
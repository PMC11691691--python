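"""End-to-end driver: simulate -> decode -> RSA / behavior / commonality -> stats.

``run_pipeline`` executes the requested stages on a synthetic experiment
described by a :class:`~hemidyn.config.RunConfig`, writes CSV/NPZ outputs and
a JSON manifest into a run directory named after the config hash (so a
changed config can never overwrite a previous run), and returns the manifest.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import commonality as com
from . import rsa
from .bayes import BFSpec, bf_timecourse, detect_onset, jackknife_ci
from .config import RunConfig
from .decode import (ElectrodeCluster, balance_word_trials, collapse_contra_ipsi,
                     mean_accuracy, pairwise_decode)
from .synth import (CONCEPTS, StimulusSet, generate_design, generate_epochs,
                    generate_triplet_responses)

__all__ = ["run_pipeline"]

_COMBOS = [("left", "LVF"), ("left", "RVF"), ("right", "LVF"), ("right", "RVF")]


def _nanmean(arrs, axis=0):
    """nanmean that tolerates all-NaN cells (masked RDM diagonals) silently."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(arrs, axis=axis)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _clusters(epochs_channels: pd.DataFrame) -> dict[str, ElectrodeCluster]:
    out = {}
    for name in ("left", "right"):
        ch = tuple(epochs_channels.loc[epochs_channels["cluster"] == name, "name"])
        out[name] = ElectrodeCluster(name, ch)
    return out


def run_pipeline(config: RunConfig) -> dict:
    stimuli = StimulusSet.make(CONCEPTS[: config.n_concepts],
                               config.n_image_exemplars, config.n_word_variants)
    sim = config.simulation
    run_dir = Path(config.out_dir) / f"run-{config.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)

    manifest: dict = {
        "config_hash": config.config_hash(),
        "run_dir": str(run_dir),
        "n_stimuli": len(stimuli),
        "n_pair_contrasts": len(stimuli) * (len(stimuli) - 1) // 2,
        "seeds": {"simulation": sim.seed, "word_balance": config.seed,
                  "image_task_triplets": config.seed + 1,
                  "concept_task_triplets": config.seed + 2,
                  "permutations": config.seed},
        "outputs": [],
    }
    analyses = set(config.analyses)
    need_splits = bool(analyses & {"rsa", "consistency", "commonality"})
    need_all = bool(analyses & {"decoding", "behavior", "commonality", "stats"})

    try:
        design = generate_design(sim, stimuli)
        balanced = balance_word_trials(design, stimuli, seed=config.seed)
    except Exception as exc:
        raise StageError(f"simulate: {exc}") from exc

    participants = sorted(balanced["participant"].unique())
    acc: dict = {}      # (condition, hemi, field) -> list of (T,) accuracy
    rdm_all: dict = {}  # (condition, hemi, field) -> list of (S,S,T) values
    rdm_split: dict = {}  # (condition, hemi, field, split) -> list of RDM series
    times = None

    for p in participants:
        try:
            epochs = generate_epochs(sim, balanced[balanced["participant"] == p], stimuli)
        except Exception as exc:
            raise StageError(f"simulate (participant {p}): {exc}") from exc
        times = epochs.times
        clusters = _clusters(epochs.channels)
        for condition in config.conditions:
            if condition not in set(epochs.trial_meta["condition"]):
                raise StageError(f"decode: condition '{condition}' absent from epochs")
            for hemi, hemifield in _COMBOS:
                try:
                    if need_all:
                        r = pairwise_decode(epochs, clusters[hemi], condition, hemifield,
                                            n_folds=config.n_folds, split="all",
                                            shrinkage=config.shrinkage)
                        acc.setdefault((condition, hemi, hemifield), []).append(
                            mean_accuracy(r).values)
                        rdm_all.setdefault((condition, hemi, hemifield), []).append(r.values)
                    if need_splits:
                        for split in ("odd", "even"):
                            r = pairwise_decode(epochs, clusters[hemi], condition,
                                                hemifield, n_folds=config.n_folds // 2,
                                                split=split, shrinkage=config.shrinkage)
                            rdm_split.setdefault(
                                (condition, hemi, hemifield, split), []).append(r)
                except Exception as exc:
                    raise StageError(
                        f"decode ({condition}/{hemi}/{hemifield}, participant {p}): {exc}"
                    ) from exc

    def _write(df: pd.DataFrame, name: str) -> None:
        path = run_dir / name
        df.to_csv(path, index=False)
        manifest["outputs"].append(name)

    if "decoding" in analyses:
        rows = []
        for (condition, hemi, hemifield), series in acc.items():
            arr = np.stack(series)
            for i, p in enumerate(participants):
                rows.append(pd.DataFrame({
                    "participant": p, "condition": condition, "hemisphere": hemi,
                    "hemifield": hemifield, "time_ms": times, "accuracy": arr[i]}))
        _write(pd.concat(rows, ignore_index=True), "accuracy_timecourses.csv")

    if "stats" in analyses:
        spec = BFSpec(prior_scale=config.prior_scale, null_interval=config.null_interval,
                      direction="greater", mu0=0.5)
        rows = []
        for condition in config.conditions:
            per_combo = {(h, f): np.stack(acc[(condition, h, f)]) for h, f in _COMBOS}
            collapsed = collapse_contra_ipsi(per_combo)
            for side, arr in collapsed.items():
                bf = bf_timecourse(arr, times, spec, zero_variance="limit")
                onset = detect_onset(bf, threshold=config.onset_threshold,
                                     run_ms=config.onset_run_ms)
                est = None
                if len(participants) >= config.jackknife_leave_out + 2:
                    est = jackknife_ci(arr, times, "onset",
                                       leave_out=config.jackknife_leave_out, spec=spec,
                                       threshold=config.onset_threshold,
                                       run_ms=config.onset_run_ms)
                mean = arr.mean(axis=0)
                pk = int(np.argmax(np.where(times >= 0, mean, -np.inf)))
                rows.append({
                    "condition": condition, "side": side, "onset_ms": onset,
                    "onset_ci_lo": est.ci_95[0] if est else None,
                    "onset_ci_hi": est.ci_95[1] if est else None,
                    "peak_time_ms": int(times[pk]), "peak_accuracy": float(mean[pk]),
                })
        _write(pd.DataFrame(rows), "onsets.csv")

    if "rsa" in analyses:
        prof_rows, bf_rows = [], []
        for condition in config.conditions:
            profiles = []
            for i, p in enumerate(participants):
                surfaces = []
                for hemifield, contra in (("LVF", "right"), ("RVF", "left")):
                    ipsi = "left" if contra == "right" else "right"
                    tg = rsa.crosscorrelate_timegen(
                        rdm_split[(condition, contra, hemifield, "odd")][i],
                        rdm_split[(condition, ipsi, hemifield, "even")][i],
                        rdm_split[(condition, contra, hemifield, "even")][i],
                        rdm_split[(condition, ipsi, hemifield, "odd")][i])
                    surfaces.append(tg.values)
                mean_tg = rsa.TimeGenMatrix(_nanmean(np.stack(surfaces)),
                                            times, times, condition)
                prof = rsa.delay_profile(mean_tg, config.delay_range, config.rsa_window)
                profiles.append(prof.values)
                for d, v in zip(prof.delays, prof.values):
                    prof_rows.append({"participant": p, "condition": condition,
                                      "delay_ms": int(d), "mean_correlation": v})
            profs = np.stack(profiles)
            delays = np.arange(config.delay_range[0], config.delay_range[1] + 1)
            if len(participants) >= 2:
                bf = rsa.asymmetry_test(profs, delays,
                                        BFSpec(prior_scale=config.prior_scale,
                                               null_interval=config.null_interval,
                                               direction="greater", mu0=0.0))
                bf["condition"] = condition
                bf_rows.append(bf)
        _write(pd.DataFrame(prof_rows), "delay_profiles.csv")
        if bf_rows:
            _write(pd.concat(bf_rows, ignore_index=True), "asymmetry_bf.csv")

    if "consistency" in analyses:
        condition = config.conditions[0]
        courses = []
        for i, p in enumerate(participants):
            rdms = {(h, f, s): rdm_split[(condition, h, f, s)][i]
                    for h, f in _COMBOS for s in ("odd", "even")}
            courses.append(rsa.consistency_within_across(rdms))
        rows = []
        for key in ("within_contra", "within_ipsi", "across"):
            mean = _nanmean(np.stack([c[key] for c in courses]))
            rows.append(pd.DataFrame({"measure": key, "time_ms": times,
                                      "mean_correlation": mean}))
        _write(pd.concat(rows, ignore_index=True), "consistency.csv")

    behavioral_rdms = {}
    if analyses & {"behavior", "commonality"}:
        models = beh.build_model_rdms(stimuli)
        for task, tc in (("image", config.image_task), ("concept", config.concept_task)):
            resp = generate_triplet_responses(
                [models["image_model"].values, models["concept_model"].values],
                [tc.w_image, tc.w_concept], tc.n_participants, tc.n_trials,
                tc.decision_noise, seed=config.seed + (1 if task == "image" else 2),
                task=task)
            behavioral_rdms[task] = beh.build_rdm_from_triplets(resp, len(stimuli))

    if "behavior" in analyses:
        rows = []
        named = {"image_task": behavioral_rdms["image"],
                 "concept_task": behavioral_rdms["concept"], **models}
        keys = list(named)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                res = beh.correlate_rdms(named[a], named[b])
                rows.append({"a": a, "b": b, "rho": res.rho, "n_pairs": res.n_pairs})
        corr = {(r["a"], r["b"]): r["rho"] for r in rows}

        def rho(a, b):
            return corr.get((a, b), corr.get((b, a)))

        z_img = beh.compare_dependent_correlations(
            rho("image_task", "image_model"), rho("concept_task", "image_model"),
            rho("image_task", "concept_task"), behavioral_rdms["image"].n_stimuli
            * (behavioral_rdms["image"].n_stimuli - 1) // 2)
        rows.append({"a": "steiger_image_model", "b": "image_vs_concept_task",
                     "rho": z_img.z, "n_pairs": z_img.n})
        _write(pd.DataFrame(rows), "behavior_correlations.csv")

    if analyses & {"behavior", "commonality"} and rdm_all:
        condition = config.conditions[0]
        per_combo = {(h, f): _nanmean(np.stack(rdm_all[(condition, h, f)]))
                     for h, f in _COMBOS}
        collapsed = collapse_contra_ipsi(per_combo)

        if "behavior" in analyses:
            rows = []
            for side, values in collapsed.items():
                iu = np.triu_indices(values.shape[0], k=1)
                cells = values[iu]
                for task, rdm in behavioral_rdms.items():
                    vb = rdm.pair_vector()
                    ok = np.isfinite(vb)
                    series = rsa.spearman_columns(
                        cells[ok], np.repeat(vb[ok, None], cells.shape[1], axis=1))
                    rows.append(pd.DataFrame({"side": side, "task": task,
                                              "time_ms": times, "rho": series}))
            _write(pd.concat(rows, ignore_index=True), "neural_behavior.csv")

        if "commonality" in analyses:
            rows = []
            for side, values in collapsed.items():
                res = com.permutation_test(values, behavioral_rdms["image"].pair_vector(),
                                           behavioral_rdms["concept"].pair_vector(),
                                           n_permutations=config.n_permutations,
                                           seed=config.seed)
                obs = res.observed
                rows.append(pd.DataFrame({
                    "side": side, "time_ms": times,
                    "r2_full": np.atleast_1d(obs.r2_full),
                    "unique_image": np.atleast_1d(obs.unique_image),
                    "unique_concept": np.atleast_1d(obs.unique_concept),
                    "common": np.atleast_1d(obs.common),
                    "p_unique_image": res.p_values["unique_image"],
                    "p_unique_concept": res.p_values["unique_concept"],
                    "p_common": res.p_values["common"],
                }))
            _write(pd.concat(rows, ignore_index=True), "commonality.csv")

    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
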
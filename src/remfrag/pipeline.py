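"""End-to-end orchestration: simulate -> score -> epoch -> ERSP -> clusters ->
autonomic -> memory -> models -> brain-behavior correlation.

Runs the full analysis chain on a synthetic cohort and assembles a report
with the four verification surfaces of the analysis: the sleep-parameter
comparison table, the stage-transition t-matrix, the stimulation-locked
band topographies with cluster inference, the HRD mixed-model contrasts,
and the alpha-topography/HRD-change correlation clusters.  Deterministic
under a fixed seed (the report carries seed and a config hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import autonomic as au
from . import clusters as cl
from . import epochs as epo
from . import hypnogram as hyp
from . import io as rio
from . import models as mod
from . import sdt
from . import simulate as sim
from . import timefreq as tf


@dataclass(frozen=True)
class RunConfig:
    cohort: sim.CohortConfig = field(default_factory=sim.CohortConfig)
    n_permutations: int = 5000
    cluster_alpha: float = 0.05
    alpha: float = 0.05
    out_dir: str | None = None
    #: trial-level reactivity models carry the stimulus random intercept
    stimulus_random: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def sleep_stage_report(config: sim.CohortConfig) -> dict:
    """Macrostructure table and transition-matrix comparison of the cohort."""
    macro = {c: [] for c in sim.CONDITIONS}
    mats = {c: [] for c in sim.CONDITIONS}
    hypnos = {}
    for s in range(config.n_subjects):
        for cond in sim.CONDITIONS:
            h, ev = sim.generate_hypnogram(config, s, cond)
            hypnos[(s, cond)] = (h, ev)
            macro[cond].append(hyp.score_macrostructure(h, ev).as_series())
            mats[cond].append(hyp.transition_matrix(h))
    tables = {c: pd.DataFrame(macro[c]) for c in sim.CONDITIONS}
    comparison = {}
    for var in ("TST", "SE", "N1_min", "REM_min", "N1_pct", "REM_pct", "REMfr"):
        a = tables["FRG"][var].to_numpy(float)
        b = tables["CTR"][var].to_numpy(float)
        t, p = sp_stats.ttest_rel(a, b)
        comparison[var] = {
            "FRG_mean": float(np.mean(a)), "CTR_mean": float(np.mean(b)),
            "difference": float(np.mean(a - b)), "t": float(t), "p": float(p),
        }
    mc = hyp.compare_transition_matrices(mats["FRG"], mats["CTR"])
    return {
        "macro": tables, "comparison": comparison, "transition": mc,
        "hypnograms": hypnos,
        "matrices": mats,
    }


def eeg_report(
    config: sim.CohortConfig, hypnos: dict, n_permutations: int,
    cluster_alpha: float, alpha: float, seed,
) -> dict:
    """Per-subject ERSP band topographies and their cluster inference."""
    ch_names = config.eeg.ch_names
    pos = rio.montage_positions(ch_names, config.eeg.montage)
    adjacency = cl.adjacency_from_positions(pos, list(ch_names))
    topo = {b: [] for b in tf.BANDS}
    truths = []
    tf_channel = "Pz" if "Pz" in ch_names else ch_names[len(ch_names) // 2]
    tf_maps = []
    ersp_axes = None
    n_outside_rem = 0
    for s in range(config.n_subjects):
        h, ev = hypnos[(s, "FRG")]
        selection = epo.select_epochs(ev, h)
        n_outside_rem += selection.n_dropped("outside_REM")
        n_ep = min(len(selection.kept), config.eeg.max_epochs_per_subject)
        n_ep = max(n_ep, 2)
        eps, truth = sim.generate_eeg_epochs(config, s, n_ep)
        ersp = tf.baseline_db(tf.morlet_ersp(eps, config.eeg.sfreq))
        for b, bt in tf.band_topographies(ersp, ch_names=ch_names).items():
            topo[b].append(bt.values)
        tf_maps.append(ersp.values[ch_names.index(tf_channel)])
        ersp_axes = (ersp.freqs, ersp.times_ms)
        truths.append(truth)
    maps = {b: np.vstack(v) for b, v in topo.items()}
    rng = np.random.default_rng(seed)
    tests = {
        b: cl.topo_cluster_test(
            maps[b], adjacency, n_permutations=n_permutations,
            cluster_alpha=cluster_alpha, alpha=alpha, seed=rng,
        )
        for b in tf.BANDS
    }
    # time-frequency cluster test at one representative midline channel
    tf_test = cl.tf_cluster_test(
        np.stack(tf_maps), ersp_axes[1], ersp_axes[0],
        n_permutations=min(n_permutations, 500),
        cluster_alpha=cluster_alpha, alpha=alpha, seed=rng,
    )
    return {"maps": maps, "tests": tests, "adjacency": adjacency,
            "truths": truths, "n_outside_rem_drops": n_outside_rem,
            "ch_names": ch_names, "tf_test": tf_test, "tf_channel": tf_channel}


def autonomic_report(config: sim.CohortConfig, stimulus_random: bool) -> dict:
    """Trial metrics, non-responder screening and the reactivity mixed models."""
    frames = []
    for s in range(config.n_subjects):
        for cond in sim.CONDITIONS:
            for sess in sim.SESSIONS:
                trials = sim.generate_autonomic_trials(config, s, cond, sess)
                m = au.trial_metrics(trials)
                m.insert(0, "subject", s)
                m["stimulus_id"] = m["condition"] + "_" + m["trial"].astype(str)
                frames.append(m)
    table = pd.concat(frames, ignore_index=True)
    screen = au.screen_nonresponders(table)
    kept = set(screen.loc[screen["keep"], "subject"])
    hrd_fit = mod.fit_and_contrast(
        table, mod.LmmSpec("hrd", stimulus_random=stimulus_random))
    eda_table = table[table["subject"].isin(kept)].copy()
    eda_table["cda_scr"] = eda_table["cda_scr"].astype(float)
    scr_fit = mod.fit_and_contrast(
        eda_table, mod.LmmSpec("cda_scr", stimulus_random=stimulus_random))
    return {"trials": table, "screen": screen, "hrd_fit": hrd_fit,
            "scr_fit": scr_fit}


def memory_report(config: sim.CohortConfig) -> dict:
    frames = []
    for s in range(config.n_subjects):
        for cond in sim.CONDITIONS:
            for sess in sim.SESSIONS:
                r = sim.generate_recognition(config, s, cond, sess)
                r.insert(0, "subject", s)
                frames.append(r)
    responses = pd.concat(frames, ignore_index=True)
    dp = sdt.dprime_table(responses,
                          by=["subject", "condition", "session", "stimulus_type"])
    fit = mod.fit_and_contrast(dp, mod.LmmSpec("dprime", stimulus_random=False))
    return {"responses": responses, "dprime": dp, "fit": fit}


def delta_hrd(trials: pd.DataFrame, condition: str = "FRG",
              later: str = "T1") -> pd.Series:
    """Per-subject HRD change (later session minus baseline) in one condition."""
    sub = trials[trials["condition"] == condition]
    m = sub.groupby(["subject", "session"])["hrd"].mean().unstack("session")
    return m[later] - m["T0"]


def correlation_report(
    eeg: dict, trials: pd.DataFrame, n_permutations: int, cluster_alpha: float,
    alpha: float, seed,
) -> dict:
    """Cluster-corrected band-topography x HRD-change correlations (T1 and T2)."""
    out = {}
    rng = np.random.default_rng(seed)
    for later in ("T1", "T2"):
        d = delta_hrd(trials, "FRG", later).to_numpy(float)
        out[later] = {
            b: cl.topo_cluster_correlation(
                eeg["maps"][b], d, eeg["adjacency"],
                n_permutations=n_permutations, cluster_alpha=cluster_alpha,
                alpha=alpha, seed=rng,
            )
            for b in tf.BANDS
        }
        out[f"delta_{later}"] = d
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on the synthetic cohort and build the run report."""
    cohort = config.cohort
    report: dict = {
        "seed": cohort.seed,
        "config_hash": config.config_hash(),
        "n_subjects": cohort.n_subjects,
    }
    stage = "sleep"
    try:
        sleep = sleep_stage_report(cohort)
        stage = "eeg"
        eeg = eeg_report(cohort, sleep["hypnograms"], config.n_permutations,
                         config.cluster_alpha, config.alpha,
                         seed=(cohort.seed, 7001))
        stage = "autonomic"
        auto = autonomic_report(cohort, config.stimulus_random)
        stage = "memory"
        mem = memory_report(cohort)
        stage = "correlation"
        corr = correlation_report(eeg, auto["trials"], config.n_permutations,
                                  config.cluster_alpha, config.alpha,
                                  seed=(cohort.seed, 7002))
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    mcomp = sleep["transition"]
    report["sleep"] = {
        "comparison": sleep["comparison"],
        "transition_t": mcomp.t,
        "transition_p_bonferroni": mcomp.p_bonferroni,
        "significant_cells": [
            (hyp.STAGES[i], hyp.STAGES[j])
            for i, j in zip(*np.where(mcomp.significant()))
        ],
    }
    report["eeg"] = {
        "band_mean_db": {b: eeg["maps"][b].mean(axis=0) for b in tf.BANDS},
        "cluster_p": {
            b: [c.p for c in eeg["tests"][b].clusters] for b in tf.BANDS
        },
        "significant_bands": [
            b for b in tf.BANDS if eeg["tests"][b].significant()
        ],
        "tf_channel": eeg["tf_channel"],
        "tf_significant_clusters": len(eeg["tf_test"].significant()),
        "tf_min_p": min((c.p for c in eeg["tf_test"].clusters), default=1.0),
        "n_outside_rem_drops": eeg["n_outside_rem_drops"],
    }
    report["autonomic"] = {
        "screen": auto["screen"],
        "hrd_effects": auto["hrd_fit"].effects,
        "hrd_contrasts": auto["hrd_fit"].contrasts,
        "hrd_interaction_significant": auto["hrd_fit"].interaction_significant,
        "scr_interaction_significant": auto["scr_fit"].interaction_significant,
        "hrd_cell_means": auto["trials"].groupby(
            ["condition", "session"])["hrd"].mean(),
    }
    report["memory"] = {
        "dprime_session_means": mem["dprime"].groupby("session")["dprime"].mean(),
        "condition_effect_p": float(
            mem["fit"].effects.set_index("term").at["C(condition)", "p"]),
        "interaction_significant": mem["fit"].interaction_significant,
    }
    report["correlation"] = {
        later: {
            "significant_bands": [
                b for b in tf.BANDS if corr[later][b].significant()
            ],
            "alpha_clusters": corr[later]["alpha"].to_dict(),
        }
        for later in ("T1", "T2")
    }
    report["_objects"] = {"sleep": sleep, "eeg": eeg, "autonomic": auto,
                          "memory": mem, "correlation": corr}

    if config.out_dir:
        _write_report(report, config)
    return report


def _write_report(report: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obj = report["_objects"]
    obj["autonomic"]["trials"].to_csv(out / "autonomic_trials.tsv",
                                      sep="\t", index=False)
    obj["memory"]["dprime"].to_csv(out / "dprime.tsv", sep="\t", index=False)
    slim = {
        k: v for k, v in report.items() if k != "_objects"
    }
    slim["sleep"] = dict(slim["sleep"])
    rio.write_json(_as_jsonable(_strip_frames(slim)), out / "report.json")


def _strip_frames(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, pd.Series):
        return {str(k): v for k, v in obj.items()}
    if isinstance(obj, dict):
        return {str(k): _strip_frames(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_strip_frames(v) for v in obj]
    return obj
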
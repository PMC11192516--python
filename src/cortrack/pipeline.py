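"""End-to-end orchestration: simulate -> preprocess -> tag -> erp -> stats.

``run_pipeline`` streams one subject at a time (simulate, preprocess,
reduce to per-subject scalars) so a full two-group cohort fits comfortably
in memory, then runs the group-level statistics and writes deterministic
TSV/JSON reports.  Timestamps only ever go to the log file, so numeric
reports are byte-reproducible given the master seed.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import paradigm as par
from .erp import condition_erps, pointwise_fdr_map, roi_window_effect
from .io import (
    dump_json,
    validate_config,
    write_cohort_table,
)
from .montage import Montage, standard_64
from .preprocess import (
    baseline_correct,
    drop_channels,
    epoch_by_events,
    fir_bandpass,
    rereference,
    reject_epochs,
)
from .stats import correlate_measures, independent_t
from .synth import (
    CohortSpec,
    SubjectParams,
    draw_cohort,
    inject_artifacts,
    simulate_entrainment,
    simulate_n400,
)
from .tagging import (
    evoked_average,
    evoked_power,
    group_peak_test,
    neighbor_normalize,
    subject_peak_pair,
)

log = logging.getLogger("cortrack.pipeline")

__all__ = [
    "run_pipeline",
    "build_montage",
    "cohort_spec_from_config",
    "entrainment_subject_pairs",
    "entrainment_group_results",
    "n400_subject_analysis",
]


def build_montage(cfg: dict) -> Montage:
    m = standard_64()
    channels = cfg.get("montage", {}).get("channels")
    if channels:
        m = m.subset(channels)
    return m


def cohort_spec_from_config(cfg: dict, group: str, master_seed: int) -> CohortSpec:
    gc = cfg["cohorts"][group]
    return CohortSpec(
        group=group,
        n_subjects=int(gc["n_subjects"]),
        coupling_rho=float(gc["coupling_rho"]),
        behavior_coupling_rho=float(gc.get("behavior_coupling_rho", 0.0)),
        n400_latency_ms=float(gc["n400_latency_ms"]),
        artifact_rate=float(gc["artifact_rate"]),
        master_seed=master_seed,
        distributions={k: tuple(v) for k, v in gc["distributions"].items()},
    )


# ---------------------------------------------------------------------
# per-subject analyses (shared by the pipeline and the validation
# experiments so both exercise identical code paths)
# ---------------------------------------------------------------------


def entrainment_subject_pairs(
    sp: SubjectParams,
    spec: par.ParadigmSpec,
    m: Montage,
    band_hz: tuple[float, float] = (0.1, 25.0),
    k: int = 2,
    exclude: list[str] | None = None,
    gap_s: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Full single-subject entrainment analysis -> rate: (peak, neigh) dB."""
    rec = simulate_entrainment(sp, spec, m, gap_s=gap_s)
    if exclude:
        rec = drop_channels(rec, exclude)
    rec = fir_bandpass(rec, *band_hz)
    rec = rereference(rec, "common_average")
    sent_dur = par.sentence_duration(spec)
    trial_dur = spec.sentences_per_trial * sent_dur
    tmin = sent_dur if spec.drop_first_sentence else 0.0
    es = epoch_by_events(rec, "trial", tmin, trial_dur)
    avg = evoked_average(es)
    ss = evoked_power(
        avg, spec.fs_hz, subject_id=sp.subject_id,
        channel_labels=es.channel_labels,
        expected_len=int(round(par.epoch_duration(spec) * spec.fs_hz)),
    )
    ss = neighbor_normalize(ss, k)
    bins = par.tag_bins(spec)
    return {rate: subject_peak_pair(ss, b, k=k) for rate, b in bins.items()}


def entrainment_group_results(
    subjects: list[SubjectParams],
    spec: par.ParadigmSpec,
    m: Montage,
    band_hz: tuple[float, float] = (0.1, 25.0),
    k: int = 2,
    alpha: float = 0.05,
    exclude: list[str] | None = None,
    gap_s: float = 1.0,
):
    """Per-rate one-tailed peak tests for a cohort; also returns the pairs."""
    all_pairs: dict[str, list[tuple[float, float]]] = {
        r: [] for r in par.RATE_MULTIPLIERS
    }
    for sp in subjects:
        pairs = entrainment_subject_pairs(
            sp, spec, m, band_hz=band_hz, k=k, exclude=exclude, gap_s=gap_s
        )
        for rate, pair in pairs.items():
            all_pairs[rate].append(pair)
    results = {
        rate: group_peak_test(np.array(p), alpha=alpha, label=rate)
        for rate, p in all_pairs.items()
    }
    return results, all_pairs


def n400_subject_analysis(
    sp: SubjectParams,
    m: Montage,
    cfg_n400: dict,
    fs_hz: float,
    exclude: list[str] | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, float], float, list[str]]:
    """Full single-subject N400 analysis.

    Returns (condition ERPs, window-mean effects per window label,
    rejected fraction, channel labels of the ERPs).
    """
    rec = simulate_n400(
        sp,
        int(cfg_n400["n_sentences_per_condition"]),
        m,
        isi_s=float(cfg_n400.get("isi_s", 2.5)),
        fs_hz=fs_hz,
    )
    rec = inject_artifacts(rec, sp, window_s=tuple(cfg_n400["epoch_s"]))
    if exclude:
        rec = drop_channels(rec, exclude)
    rec = fir_bandpass(rec, *cfg_n400["band_hz"])
    mastoids = tuple(cfg_n400.get("mastoids", ("M1", "M2")))
    rec = rereference(rec, "linked_mastoids", mastoid_labels=mastoids)
    rec = drop_channels(rec, mastoids)
    tmin, tmax = cfg_n400["epoch_s"]
    es = epoch_by_events(rec, ("congruent", "incongruent"), tmin, tmax)
    es = baseline_correct(es, *cfg_n400["baseline_s"])
    es, rej_frac = reject_epochs(es, float(cfg_n400["reject_uv"]))
    erps = condition_erps(es)
    windows: dict[str, float] = {}
    for w0, w1 in cfg_n400["windows_ms"]:
        sl_ms = (float(w0), float(w1))
        i0 = int(round((sl_ms[0] / 1000 - tmin) * fs_hz))
        i1 = int(round((sl_ms[1] / 1000 - tmin) * fs_hz))
        roi_idx = [es.channel_labels.index(lb) for lb in cfg_n400["roi"]]
        diff = erps["incongruent"][roi_idx, i0:i1].mean() - erps["congruent"][
            roi_idx, i0:i1
        ].mean()
        windows[f"{int(w0)}_{int(w1)}"] = float(diff)
    return erps, windows, rej_frac, es.channel_labels


# ---------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------


def _peak_result_json(res) -> dict:
    return {
        "t": res.t_statistic,
        "df": res.df,
        "p_one_tailed": res.p_one_tailed,
        "significant": res.significant,
        "alpha": res.alpha,
        "mean_peak_minus_neighbors_db": float(
            np.mean(res.peaks_db - res.neighbor_means_db)
        ),
    }


def _erp_effect_json(eff) -> dict:
    return {
        "window_ms": list(eff.window_ms),
        "effect_uv": eff.effect_uv,
        "t": eff.t_statistic,
        "df": eff.df,
        "p_two_tailed": eff.p_two_tailed,
        "ci95": list(eff.ci95),
    }


def run_pipeline(
    config: dict, out_dir: str | Path, seed: int | None = None, verbose: bool = False
) -> dict:
    """Execute every stage per the config and write reports under ``out_dir``.

    ``seed`` overrides the config's ``master_seed``.  Returns a summary
    dict mirroring the on-disk reports.
    """
    cfg = validate_config(dict(config))
    if seed is not None:
        cfg = dict(cfg)
        cfg["master_seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "log.txt", verbose)
    master = int(cfg["master_seed"])
    log.info("pipeline start, master_seed=%d", master)

    spec = par.ParadigmSpec.from_dict(cfg["paradigm"])
    montage = build_montage(cfg)
    mcfg = cfg.get("montage", {})
    mastoids = list(mcfg.get("mastoids", ["M1", "M2"]))
    base_exclude = [c for c in mcfg.get("exclude", []) if c in montage.labels]
    ent_exclude = base_exclude + [c for c in mastoids if c in montage.labels]
    n400_exclude = base_exclude + [
        c for c in mcfg.get("frontal_exclude", []) if c in montage.labels
    ]
    ecfg = cfg["entrainment"]
    ncfg = dict(cfg["n400"])
    ncfg.setdefault("mastoids", mcfg.get("mastoids", ["M1", "M2"]))

    groups = sorted(cfg["cohorts"])
    group_seeds = {
        g: int(c.generate_state(1)[0] & 0x7FFFFFFF)
        for g, c in zip(groups, np.random.SeedSequence(master).spawn(len(groups)))
    }

    rows = []
    summary: dict = {"master_seed": master, "groups": {}}
    for group in groups:
        cs = cohort_spec_from_config(cfg, group, group_seeds[group])
        subjects = draw_cohort(cs)
        log.info("group %s: %d subjects (seed %d)", group, len(subjects), cs.master_seed)

        dump_json(
            [
                {k: getattr(sp, k) for k in (
                    "subject_id", "group", "amp_sentential", "amp_phrasal",
                    "amp_syllabic", "n400_effect", "n400_latency_ms",
                    "noise_scale", "artifact_rate", "seed",
                )}
                for sp in subjects
            ],
            out / f"ground_truth_{group}.json",
        )

        ent_pairs: dict[str, list[tuple[float, float]]] = {
            r: [] for r in par.RATE_MULTIPLIERS
        }
        erps_all, windows_all, rej_all = [], [], []
        erp_channels: list[str] = []
        for sp in subjects:
            pairs = entrainment_subject_pairs(
                sp, spec, montage,
                band_hz=tuple(ecfg["band_hz"]),
                k=int(ecfg["neighbor_k"]),
                exclude=ent_exclude,
                gap_s=float(ecfg.get("gap_s", 1.0)),
            )
            for rate, pair in pairs.items():
                ent_pairs[rate].append(pair)
            erps, windows, rej, erp_channels = n400_subject_analysis(
                sp, montage, ncfg, spec.fs_hz, exclude=n400_exclude
            )
            erps_all.append(erps)
            windows_all.append(windows)
            rej_all.append(rej)
            log.info("subject %s done (rejected %.1f%%)", sp.subject_id, 100 * rej)

        ent_results = {
            rate: group_peak_test(
                np.array(p), alpha=float(ecfg["alpha"]), label=rate
            )
            for rate, p in ent_pairs.items()
        }
        dump_json(
            {r: _peak_result_json(res) for r, res in ent_results.items()},
            out / f"entrainment_{group}.json",
        )

        tmin = float(ncfg["epoch_s"][0])
        effects = {}
        for w0, w1 in ncfg["windows_ms"]:
            eff = roi_window_effect(
                erps_all, list(ncfg["roi"]), (float(w0), float(w1)),
                erp_channels, spec.fs_hz, tmin,
            )
            effects[f"{int(w0)}_{int(w1)}"] = eff
        pw = pointwise_fdr_map(
            erps_all, spec.fs_hz, tmin, erp_channels, q=float(ncfg["fdr_q"])
        )
        roi_idx = [erp_channels.index(lb) for lb in ncfg["roi"]]
        roi_sig = pw.mask[roi_idx].any(axis=0)
        earliest = (
            float(pw.times_s[roi_sig][0]) if roi_sig.any() else None
        )
        dump_json(
            {
                "windows": {k: _erp_effect_json(e) for k, e in effects.items()},
                "mean_rejected_fraction": float(np.mean(rej_all)),
                "pointwise": {
                    "q": pw.q,
                    "n_significant": int(pw.mask.sum()),
                    "n_tests": int(pw.mask.size),
                    "earliest_significant_roi_time_s": earliest,
                },
            },
            out / f"erp_{group}.json",
        )

        for i, sp in enumerate(subjects):
            d = {
                "subject_id": sp.subject_id,
                "group": group,
                "comprehension_rating": sp.comprehension_rating,
                "question_accuracy": sp.question_accuracy,
                "listening_score": sp.listening_score,
            }
            for rate in par.RATE_MULTIPLIERS:
                peak, neigh = ent_pairs[rate][i]
                d[f"{rate}_db"] = peak - neigh
            for wk, val in windows_all[i].items():
                d[f"n400_{wk}_uv"] = val
            rows.append(d)

        summary["groups"][group] = {
            "entrainment": {
                r: _peak_result_json(res) for r, res in ent_results.items()
            },
            "erp": {k: _erp_effect_json(e) for k, e in effects.items()},
            "mean_rejected_fraction": float(np.mean(rej_all)),
            "earliest_significant_roi_time_s": earliest,
        }

    table = pd.DataFrame(rows)
    write_cohort_table(table, out / "cohort_table.tsv")

    # correlations (second-language group when present, else first group)
    corr_group = "SL" if "SL" in groups else groups[0]
    sub = table[table["group"] == corr_group]
    pairs_cfg = [
        tuple(p) for p in cfg.get("correlation", {}).get("pairs", [])
    ] or None
    corrs = correlate_measures(sub.reset_index(drop=True), pairs_cfg)
    dump_json(
        [
            {"x": c.x_label, "y": c.y_label, "rho": c.rho, "n": c.n,
             "p_two_tailed": c.p_two_tailed}
            for c in corrs
        ],
        out / f"correlations_{corr_group}.json",
    )
    summary["correlations"] = {
        f"{c.x_label}~{c.y_label}": {"rho": c.rho, "p": c.p_two_tailed}
        for c in corrs
    }

    if len(groups) == 2:
        g1, g2 = groups
        behav = {}
        for col in ("comprehension_rating", "question_accuracy"):
            x = table.loc[table["group"] == g1, col].to_numpy()
            y = table.loc[table["group"] == g2, col].to_numpy()
            t, df, p = independent_t(x, y)
            behav[col] = {
                "groups": [g1, g2], "t": t, "df": df, "p_two_tailed": p,
                "means": [float(x.mean()), float(y.mean())],
            }
        dump_json(behav, out / "behavior.json")
        summary["behavior"] = behav

    dump_json(summary, out / "summary.json")
    log.info("pipeline done")
    return summary


def _setup_logging(path: Path, verbose: bool) -> None:
    root = logging.getLogger("cortrack")
    root.setLevel(logging.DEBUG if verbose else logging.INFO)
    for h in list(root.handlers):
        root.removeHandler(h)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    fh = logging.FileHandler(path, mode="w")
    fh.setFormatter(fmt)
    root.addHandler(fh)
    if verbose:
        sh = logging.StreamHandler(sys.stderr)
        sh.setFormatter(fmt)
        root.addHandler(sh)
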
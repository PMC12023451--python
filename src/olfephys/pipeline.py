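"""End-to-end orchestration: synthesize or load cohorts, measure, compare, report.

`make_demo_dataset` writes two synthetic cohorts (wild-type-like and
knockout-like presets: the KO preset has a lower rheobase and a more
hyperpolarized spike threshold, higher input resistance, and a higher
spontaneous-event rate) plus behavioral sessions, each with ground-truth
files.  `run_pipeline` consumes such a dataset and produces per-cell
intrinsic-property tables, event tables and summaries, balanced-bootstrap
CPD / permutation-KS group reports, behavioral block and ROC tables, and a
manifest recording seeds and a config hash so a re-run reproduces every
number exactly.  Per-cell failures are isolated and logged, not fatal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, events, intrinsic, resampling, synth, traces

__all__ = ["GROUP_PRESETS", "make_demo_dataset", "run_pipeline"]

# Qualitative group contrasts for the demo cohorts: the knockout-like preset
# is more excitable (lower rheobase, hyperpolarized threshold, higher Rin).
GROUP_PRESETS = {
    "WT": {
        "input_resistance": 120.0,
        "capacitance": 100.0,
        "series_resistance": 12.0,
        "sag_fraction": 0.04,
        "rheobase_true": 210.0,
        "gain_true": 0.12,
        "threshold_true": -51.0,
        "event_rate": 2.5,
        "event_amp_median": 18.0,
    },
    "KO": {
        "input_resistance": 150.0,
        "capacitance": 90.0,
        "series_resistance": 12.0,
        "sag_fraction": 0.04,
        "rheobase_true": 120.0,
        "gain_true": 0.16,
        "threshold_true": -56.0,
        "event_rate": 3.5,
        "event_amp_median": 18.0,
    },
}


def _jitter(rng: np.random.Generator, value: float, cv: float = 0.1) -> float:
    return float(value * rng.normal(1.0, cv))


def make_demo_dataset(
    outdir: str | Path,
    seed: int = 0,
    n_cells: int = 12,
    n_sessions: int = 4,
    synaptic_duration: float = 20.0,
) -> Path:
    """Write WT-like and KO-like synthetic cohorts plus sessions under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth_rows = []
    for group, preset in GROUP_PRESETS.items():
        gdir = outdir / group
        gdir.mkdir(exist_ok=True)
        for c in range(n_cells):
            cell = f"{group}_cell{c:02d}"
            cell_seed = int(rng.integers(0, 2**31 - 1))
            crng = np.random.default_rng(cell_seed)
            mem = synth.MembraneParams(
                input_resistance=_jitter(crng, preset["input_resistance"]),
                capacitance=_jitter(crng, preset["capacitance"]),
                series_resistance=_jitter(crng, preset["series_resistance"]),
                sag_fraction=preset["sag_fraction"],
                noise_sd=0.3,
            )
            spk = synth.SpikingParams(
                rheobase_true=_jitter(crng, preset["rheobase_true"], 0.15),
                gain_true=_jitter(crng, preset["gain_true"], 0.1),
                threshold_true=preset["threshold_true"] + crng.normal(0, 1.5),
            )
            espec = synth.EventGenSpec(
                rate=_jitter(crng, preset["event_rate"], 0.2),
                amplitude_dist=("lognormal", {"median": preset["event_amp_median"], "sigma": 0.35}),
                min_amplitude=8.0,
                duration=synaptic_duration,
            )
            sub = int(cell_seed)
            passive = synth.gen_passive_step_traces(
                mem, synth.StepProtocol([-60, -50, -40, -30, -20]), seed=sub,
                cell_id=cell, group_label=group,
            )
            tau_prot = synth.gen_passive_step_traces(
                mem, synth.StepProtocol([-20.0] * 10, duration=0.1), seed=sub + 1,
                cell_id=cell, group_label=group,
            )
            vc = synth.gen_vc_test_pulses(
                dataclasses.replace(mem, noise_sd=2.0), seed=sub + 2,
                cell_id=cell, group_label=group,
            )
            sag = synth.gen_passive_step_traces(
                mem, synth.StepProtocol([-120, -150, -180, -210]), seed=sub + 3,
                cell_id=cell, group_label=group,
            )
            fi = synth.gen_spiking_traces(
                spk, synth.StepProtocol(list(range(25, 626, 50))), membrane=mem,
                seed=sub + 4, cell_id=cell, group_label=group,
            )
            lo = max(5.0, spk.rheobase_true - 25)
            fine = synth.gen_spiking_traces(
                spk, synth.StepProtocol(list(np.arange(lo, spk.rheobase_true + 26, 5.0))),
                membrane=mem, seed=sub + 5, cell_id=cell, group_label=group,
            )
            syn_trace, syn_truth = synth.gen_synaptic_trace(espec, seed=sub + 6)
            syn_trace = dataclasses.replace(syn_trace, cell_id=cell, group_label=group)
            for name, sweeps in [
                ("passive", passive), ("tau", tau_prot), ("vc", vc),
                ("sag", sag), ("fi", fi), ("rheo_fine", fine),
            ]:
                traces.save_traces(sweeps, gdir / f"{cell}_{name}.h5")
            traces.save_traces(traces.SweepSet([syn_trace], "synaptic"), gdir / f"{cell}_synaptic.h5")
            syn_truth.to_csv(gdir / f"{cell}_synaptic_truth.csv", index=False)
            truth_rows.append(
                {
                    "cell_id": cell, "group": group, "seed": cell_seed,
                    "input_resistance": mem.input_resistance, "capacitance": mem.capacitance,
                    "tau_ms": mem.tau_ms, "series_resistance": mem.series_resistance,
                    "sag_fraction": mem.sag_fraction, "rheobase_true": spk.rheobase_true,
                    "gain_true": spk.gain_true, "threshold_true": spk.threshold_true,
                    "event_rate": espec.rate,
                }
            )
        # behavioral sessions: learning curves reaching high performance late
        sdir = outdir / f"sessions_{group}"
        sdir.mkdir(exist_ok=True)
        p_plus = np.linspace(0.55, 0.97, 10)
        p_minus = np.linspace(0.45, 0.05, 10)
        if group == "KO":
            p_plus = np.linspace(0.55, 0.9, 10)
        for s in range(n_sessions):
            spec = synth.SessionSpec(
                p_lick_csplus=p_plus, p_lick_csminus=p_minus,
                lick_semantics="trial", seed=int(rng.integers(0, 2**31 - 1)),
            )
            traces.save_session_log(synth.gen_session(spec), sdir / f"session{s:02d}.csv")
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.csv", index=False)
    (outdir / "dataset.json").write_text(
        json.dumps({"seed": seed, "n_cells": n_cells, "n_sessions": n_sessions,
                    "groups": list(GROUP_PRESETS)}, indent=1)
    )
    return outdir


def _measure_cell(gdir: Path, cell: str) -> dict:
    row: dict = {"cell_id": cell}
    vc = traces.load_traces(gdir / f"{cell}_vc.h5")
    rs, qc = intrinsic.series_resistance_qc(vc)
    row.update(series_resistance=rs, qc_pass=qc, capacitance=intrinsic.capacitance(vc))
    passive = traces.load_traces(gdir / f"{cell}_passive.h5")
    row["input_resistance"] = intrinsic.input_resistance(passive)
    row["tau_ms"] = intrinsic.time_constant(traces.load_traces(gdir / f"{cell}_tau.h5"))
    _, row["sag_percent"] = intrinsic.sag_ratio(traces.load_traces(gdir / f"{cell}_sag.h5"))
    fic = intrinsic.fi_curve(traces.load_traces(gdir / f"{cell}_fi.h5"))
    row["gain"] = fic.gain
    fine = traces.load_traces(gdir / f"{cell}_rheo_fine.h5")
    row["rheobase"] = intrinsic.rheobase(fine)
    spiking = []
    for t in fine:
        s = intrinsic.detect_spikes(t)
        if np.any((s >= t.stimulus.onset) & (s < t.stimulus.offset)):
            spiking.append(t)
    if spiking:
        first = min(spiking, key=lambda t: t.stimulus.amplitude)
        ap = intrinsic.ap_features(first)
        row.update(
            ap_threshold=ap.threshold, ap_amplitude=ap.amplitude, ap_overshoot=ap.overshoot,
            ap_half_width=ap.half_width, ap_fahp=ap.fahp, ap_latency=ap.latency,
        )
    return row


def run_pipeline(config: dict) -> dict:
    """Run the full analysis over a demo-format dataset directory.

    Required config keys: ``data_dir``, ``outdir``, ``seed``.  Optional:
    ``cpd_iterations`` (default 200), ``permutations`` (default 199),
    ``properties`` (event properties to compare, default amplitude and IEI).
    Returns the manifest (also written to ``outdir/manifest.json``).
    """
    for key in ("data_dir", "outdir", "seed"):
        if key not in config:
            raise ValueError(f"config is missing required key {key!r}")
    data_dir = Path(config["data_dir"])
    if not data_dir.exists():
        raise FileNotFoundError(f"data_dir {data_dir} does not exist")
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    iters = int(config.get("cpd_iterations", 200))
    perms = int(config.get("permutations", 199))
    props = config.get("properties", ["amplitude", "iei"])
    ds_meta = json.loads((data_dir / "dataset.json").read_text())
    groups = ds_meta["groups"]
    t0 = time.time()
    errors: dict[str, str] = {}

    intrinsic_rows, event_frames, cell_values = [], [], {p: {g: [] for g in groups} for p in props}
    for group in groups:
        gdir = data_dir / group
        for h5 in sorted(gdir.glob("*_vc.h5")):
            cell = h5.name[: -len("_vc.h5")]
            try:
                row = _measure_cell(gdir, cell)
                row["group"] = group
                intrinsic_rows.append(row)
            except Exception as exc:  # isolate per-cell failures
                errors[f"intrinsic:{cell}"] = str(exc)
            try:
                syn = traces.load_traces(gdir / f"{cell}_synaptic.h5")[0]
                evs = events.detect_events(syn)
                event_frames.append(events.events_to_frame(evs, cell, group))
                train = events.build_train(evs, cell, group)
                amps = [e.peak_amplitude for e in train.events]
                if "amplitude" in props and amps:
                    cell_values["amplitude"][group].append(np.asarray(amps))
                if "iei" in props and train.inter_event_intervals.size:
                    cell_values["iei"][group].append(train.inter_event_intervals)
            except Exception as exc:
                errors[f"events:{cell}"] = str(exc)
    pd.DataFrame(intrinsic_rows).to_csv(outdir / "intrinsic.csv", index=False)
    if event_frames:
        ev_all = pd.concat(event_frames, ignore_index=True)
        ev_all.to_csv(outdir / "events.csv", index=False)
        acc = ev_all[ev_all.status == "accepted"]
        acc.groupby(["group", "cell_id"]).agg(
            n_events=("amplitude_pA", "size"), mean_amplitude=("amplitude_pA", "mean"),
            mean_rise=("rise_ms", "mean"), mean_decay=("decay_ms", "mean"),
        ).reset_index().to_csv(outdir / "event_summary.csv", index=False)

    reports = {}
    for k, prop in enumerate(props):
        ga, gb = groups[0], groups[1]
        ca, cb = cell_values[prop][ga], cell_values[prop][gb]
        if len(ca) < 2 or len(cb) < 2:
            errors[f"stats:{prop}"] = "not enough cells with events in both groups"
            continue
        npc = resampling.default_n_per_cell(ca + cb)
        res = resampling.permutation_ks(
            ca, cb, n_per_cell=npc, iterations=iters, n_permutations=perms, seed=seed + 100 + k
        )
        cpd_a = resampling.bootstrap_cpd(ca, iterations=iters, n_per_cell=npc, seed=seed + 200 + k)
        cpd_b = resampling.bootstrap_cpd(cb, iterations=iters, n_per_cell=npc, seed=seed + 300 + k)
        report = {
            "property": prop, "groups": [ga, gb], "n_per_cell": npc,
            "observed_D_mean": res.observed_mean, "observed_D_sd": res.observed_sd,
            "p_value": res.p_value, "n_iterations": res.n_iterations,
            "n_permutations": res.n_permutations,
            "cpd": {
                ga: {"grid": cpd_a.grid.tolist(), "mean_cpd": cpd_a.mean_cpd.tolist()},
                gb: {"grid": cpd_b.grid.tolist(), "mean_cpd": cpd_b.mean_cpd.tolist()},
            },
        }
        (outdir / f"cpd_ks_{prop}.json").write_text(json.dumps(report, indent=1))
        reports[prop] = {"D": res.observed_mean, "p": res.p_value}

    block_rows, roc_rows = [], []
    for group in groups:
        sdir = data_dir / f"sessions_{group}"
        for f in sorted(sdir.glob("session*.csv")):
            sess = traces.load_session_log(f)
            blocks, reached = behavior.block_performance(sess)
            for b in blocks:
                block_rows.append(
                    {"group": group, "session": f.stem, "block": b.block,
                     "percent_correct": b.percent_correct, "hits": b.hits, "misses": b.misses,
                     "false_alarms": b.false_alarms, "correct_rejections": b.correct_rejections,
                     "criterion_reached": reached}
                )
            for window in ("first60", "last60"):
                roc = behavior.roc_curve(behavior.select_window(sess, window), window)
                roc_rows.append(
                    {"group": group, "session": f.stem, "window": window,
                     "auc": roc.auc, "se_auc": roc.se_auc, "n_pos": roc.n_pos, "n_neg": roc.n_neg}
                )
    pd.DataFrame(block_rows).to_csv(outdir / "behavior_blocks.csv", index=False)
    pd.DataFrame(roc_rows).to_csv(outdir / "behavior_roc.csv", index=False)

    cfg_hash = hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {
        "config": {k: str(v) for k, v in config.items()},
        "config_sha256": cfg_hash,
        "seed": seed,
        "elapsed_s": round(time.time() - t0, 2),
        "stats": reports,
        "errors": errors,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
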
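"""End-to-end orchestration: simulate -> (re)track -> co-movement -> dwell
kinetics -> motion/rebinding, plus the profiling branch simulate -> enrich.

Runs are deterministic given the config seed: every cell/condition derives
its RNG from (seed, condition index, cell index).  Each run directory
contains the result tables (CSV/TSV), a JSON report whose every number is
traceable to the recorded config hash + seed, and a JSON-lines log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comove, dwellkin, motion, riboenrich, simulate, tracklink

__all__ = ["ConditionConfig", "RunConfig", "run_pipeline", "recovery_report"]


@dataclass
class ConditionConfig:
    label: str = "control"
    n_cells: int = 5
    sim: dict = field(default_factory=dict)   # SimConfig field overrides


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "run"
    conditions: list[ConditionConfig] = field(
        default_factory=lambda: [ConditionConfig()]
    )
    run_spt: bool = True
    run_ribo: bool = False
    relink: bool = True                      # re-link emitted spots with the LAP tracker
    coloc: dict = field(default_factory=dict)  # ColocConfig overrides
    ribo: dict = field(default_factory=dict)   # genes, length, depth, windows...

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        conds = [ConditionConfig(**c) for c in raw.pop("conditions", [])]
        cfg = cls(**{k: v for k, v in raw.items() if k != "conditions"})
        if conds:
            cfg.conditions = conds
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class _JsonlLogger:
    def __init__(self, path: Path, seed: int, config_hash: str):
        self.path = path
        self.seed = seed
        self.config_hash = config_hash
        self.path.write_text("")

    def log(self, stage: str, **extra) -> None:
        rec = {"stage": stage, "seed": self.seed, "config_hash": self.config_hash}
        rec.update(extra)
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _simulate_cell(cond: ConditionConfig, cond_idx: int, cell_idx: int,
                   seed: int) -> tuple[pd.DataFrame, simulate.GroundTruthLog, simulate.SimConfig]:
    overrides = dict(cond.sim)
    dm = overrides.pop("dwell_model", None)
    if isinstance(dm, dict):
        dm = simulate.DwellModel(**dm)
    cfg = simulate.SimConfig(**overrides)
    if dm is not None:
        cfg.dwell_model = dm
    cfg.seed = [seed, cond_idx, cell_idx]  # type: ignore[assignment]
    tracks, truth = simulate.simulate_movie(cfg)
    return tracks, truth, cfg


def _channel_tracks(tracks: pd.DataFrame, channel: str, relink: bool,
                    link_cfg: tracklink.LinkConfig) -> pd.DataFrame:
    sub = tracks[tracks["channel"] == channel][["track_id", "frame", "x_um", "y_um"]]
    if not relink:
        return sub.reset_index(drop=True)
    spots = sub[["frame", "x_um", "y_um"]]
    return tracklink.link_tracks(spots, link_cfg)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; return the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.content_hash()
    logger = _JsonlLogger(outdir / "log.jsonl", config.seed, chash)
    report: dict = {
        "seed": config.seed,
        "config_hash": chash,
        "config": config.to_dict(),
        "conditions": {},
        "ribo": "skipped",
    }
    logger.log("start", time=time.strftime("%Y-%m-%dT%H:%M:%S"))

    if config.run_spt:
        for cond_idx, cond in enumerate(config.conditions):
            try:
                report["conditions"][cond.label] = _run_condition(
                    config, cond, cond_idx, outdir, logger
                )
            except Exception as exc:  # pragma: no cover - abort path
                logger.log("error", condition=cond.label, code="E_STAGE",
                           message=str(exc))
                raise
    else:
        report["conditions"] = "skipped"

    if config.run_ribo:
        report["ribo"] = _run_ribo(config, outdir, logger)

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                                   default=_jsonable))
    logger.log("done")
    return outdir


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _run_condition(config: RunConfig, cond: ConditionConfig, cond_idx: int,
                   outdir: Path, logger: _JsonlLogger) -> dict:
    link_cfg = tracklink.LinkConfig()
    coloc_cfg = comove.ColocConfig(**config.coloc)
    events_by_cell: dict[int, list] = {}
    all_event_rows = []
    motion_rows = []
    rebind_all: list[motion.RebindCycle] = []
    n_untrackable = 0
    n_chap_tracks = 0

    for cell_idx in range(cond.n_cells):
        tracks, truth, sim_cfg = _simulate_cell(cond, cond_idx, cell_idx, config.seed)
        chap = _channel_tracks(tracks, "chaperone", config.relink, link_cfg)
        cli = _channel_tracks(tracks, "client", config.relink, link_cfg)
        dist = comove.pair_distances(chap, cli)
        spans = {
            "a": {tid: (int(g["frame"].min()), int(g["frame"].max()))
                  for tid, g in chap.groupby("track_id")},
            "b": {tid: (int(g["frame"].min()), int(g["frame"].max()))
                  for tid, g in cli.groupby("track_id")},
        }
        events = comove.extract_events(dist, coloc_cfg, track_spans=spans)
        events_by_cell[cell_idx] = events
        all_event_rows.append(comove.events_to_frame(events, cell_idx))

        for tid, g in chap.groupby("track_id"):
            if len(g) >= 11:
                stats = motion.analyze_track(int(tid), g,
                                             max_lag=10,
                                             frame_interval=sim_cfg.frame_interval)
                motion_rows.append((cell_idx, tid, stats.d, stats.alpha_exp,
                                    stats.motion_class))
        n_chap_tracks += chap["track_id"].nunique()
        cycles, untrack = motion.find_rebind_cycles(
            events, chap, cli, frame_interval=sim_cfg.frame_interval
        )
        rebind_all.extend(cycles)
        n_untrackable += untrack
        logger.log("cell", condition=cond.label, cell=cell_idx,
                   n_events=len(events))

    summary, normalized = comove.summarize_cells(events_by_cell, cond.n_cells)
    non_empty = [f for f in all_event_rows if len(f)]
    events_df = (pd.concat(non_empty, ignore_index=True)
                 if non_empty else comove.events_to_frame([], 0))
    events_df.to_csv(outdir / f"events_{cond.label}.csv", index=False)
    summary.to_csv(outdir / f"cells_{cond.label}.csv", index=False)

    durations = events_df["duration_s"].to_numpy()
    fit_block: dict = {"status": "too few events", "n_events": int(len(durations))}
    if len(durations) >= 10:
        sample = dwellkin.DwellSample(durations, t_min=coloc_cfg.min_duration,
                                      dt=coloc_cfg.frame_interval)
        fit1 = dwellkin.fit_survival(sample, "single")
        fit2 = dwellkin.fit_survival(sample, "two")
        chosen = dwellkin.select_model(fit1, fit2)
        fit_block = {
            "n_events": int(len(durations)),
            "selected_model": chosen.model,
            "selection_rule": chosen.selection_rule,
            "single": {"tau": fit1.tau, "r_squared": fit1.r_squared},
            "two": {"tau1": fit2.tau1, "tau2": fit2.tau2, "alpha": fit2.alpha,
                    "r_squared": fit2.r_squared},
        }

    motion_df = pd.DataFrame(
        motion_rows, columns=["cell", "track_id", "d_um2_s", "alpha_exp", "class"]
    )
    motion_df.to_csv(outdir / f"motion_{cond.label}.tsv", sep="\t", index=False)
    class_fracs = (motion_df["class"].value_counts(normalize=True).to_dict()
                   if len(motion_df) else {})
    trackable_off = len(rebind_all) + n_untrackable
    rebind_summary = motion.off_state_summary(
        rebind_all, n_trackable_off=max(trackable_off, 1),
        n_all_trajectories=max(n_chap_tracks, 1),
    )
    logger.log("condition", condition=cond.label,
               normalized_events=normalized)
    return {
        "n_cells": cond.n_cells,
        "events_per_cell": summary["n_events"].tolist(),
        "normalized_events": normalized,
        "survival_fit": fit_block,
        "motion_class_fractions": class_fracs,
        "motion_thresholds": dataclasses.asdict(motion.MotionThresholds()),
        "coloc_config": dataclasses.asdict(coloc_cfg),
        "rebinding": rebind_summary,
    }


def _run_ribo(config: RunConfig, outdir: Path, logger: _JsonlLogger) -> dict:
    p = {"n_genes": 20, "gene_length": 300, "input_depth": 20.0,
         "windows": [[100, 150, 8.0]], "min_run": 5, "alpha": 0.05}
    p.update(config.ribo)
    genes = []
    truths = {}
    for g in range(int(p["n_genes"])):
        windows = [tuple(w) for w in p["windows"]]
        df, truth = simulate.simulate_ribo_counts(
            int(p["gene_length"]), float(p["input_depth"]), windows,
            seed=int(np.random.SeedSequence([config.seed, 777, g]).generate_state(1)[0] % (2**31)),
            gene_id=f"g{g:04d}",
        )
        genes.append(riboenrich.CodonCounts(f"g{g:04d}", df["input_count"].to_numpy(),
                                            df["ip_count"].to_numpy()))
        truths[f"g{g:04d}"] = truth
    kept = riboenrich.coverage_filter(genes)
    rows = []
    n_called = 0
    for g in kept:
        prof = riboenrich.profile_gene(g)
        calls = riboenrich.call_interactions(prof, int(p["min_run"]), float(p["alpha"]))
        n_called += bool(calls)
        for s, e in calls:
            rows.append((g.gene, s, e,
                         float(prof.p_adj[s - 1:e].min()),
                         float(np.nanmean(prof.odds_ratio[s - 1:e]))))
    calls_df = pd.DataFrame(rows, columns=["gene", "start_codon", "end_codon",
                                           "min_p_adj", "mean_or"])
    calls_df.to_csv(outdir / "ribo_calls.tsv", sep="\t", index=False)
    logger.log("ribo", n_genes=len(genes), n_kept=len(kept), n_called=n_called)
    return {"n_genes": len(genes), "n_kept": len(kept),
            "n_genes_called": int(n_called), "params": p}


def recovery_report(
    truth: simulate.GroundTruthLog,
    events: list[comove.CoMovementEvent],
    min_frames: int = 10,
    max_duration_err_frames: int = 2,
    fitted: dwellkin.SurvivalFit | None = None,
    true_model: simulate.DwellModel | None = None,
    tau_tol: float = 0.15,
    frac_tol: float = 0.08,
) -> dict:
    """Compare detected events (simulator track ids) and fits against truth.

    Recall counts true binding events lasting >= ``min_frames`` frames with
    both partners visible throughout; a true event is recovered when a
    detected event on the same (chaperone, client) pair overlaps it in time.
    Precision is the fraction of detected events overlapping any true event.
    When a fit and the generating model are supplied, parameter biases are
    checked against the stated tolerances.
    """
    if len(truth.states):
        vis = truth.states.pivot_table(index="frame",
                                       columns=["channel", "particle_id"],
                                       values="visible", aggfunc="first")
    else:
        vis = pd.DataFrame()
    eligible = []
    for ev in truth.events.itertuples():
        n_fr = ev.release_frame - ev.bind_frame + 1
        if n_fr < min_frames:
            continue
        frames = range(ev.bind_frame, ev.release_frame + 1)
        try:
            chap_ok = all(bool(vis.loc[f, ("chaperone", ev.chaperone_id)]) for f in frames)
            cli_ok = all(bool(vis.loc[f, ("client", ev.client_id)]) for f in frames)
        except KeyError:
            chap_ok = cli_ok = False
        if chap_ok and cli_ok:
            eligible.append(ev)

    def overlaps(det, ev) -> bool:
        return (det.chaperone_track == ev.chaperone_id
                and det.client_track == ev.client_id
                and det.start_frame <= ev.release_frame
                and det.end_frame >= ev.bind_frame)

    recovered = 0
    dur_err_ok = 0
    for ev in eligible:
        hits = [d for d in events if overlaps(d, ev)]
        if hits:
            recovered += 1
            n_true = ev.release_frame - ev.bind_frame + 1
            best = min(abs(d.n_frames - n_true) for d in hits)
            if best <= max_duration_err_frames:
                dur_err_ok += 1
    true_any = list(truth.events.itertuples())
    precise = sum(1 for d in events if any(overlaps(d, ev) for ev in true_any))

    out = {
        "n_true_eligible": len(eligible),
        "n_detected": len(events),
        "recall": recovered / len(eligible) if eligible else 1.0,
        "recall_within_duration_tol": dur_err_ok / len(eligible) if eligible else 1.0,
        "precision": precise / len(events) if events else 1.0,
    }
    if fitted is not None and true_model is not None:
        if fitted.model == "single":
            bias = abs(fitted.tau - true_model.tau1) / true_model.tau1
            out["tau_bias"] = bias
            out["tau_pass"] = bool(bias <= tau_tol)
        else:
            b1 = abs(fitted.tau1 - true_model.tau1) / true_model.tau1
            b2 = abs(fitted.tau2 - true_model.tau2) / true_model.tau2
            bf = abs(fitted.alpha - true_model.alpha)
            out.update({"tau1_bias": b1, "tau2_bias": b2, "alpha_bias": bf,
                        "tau_pass": bool(b1 <= tau_tol and b2 <= tau_tol),
                        "fraction_pass": bool(bf <= frac_tol)})
        out["selection_rule"] = fitted.selection_rule
    return out
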
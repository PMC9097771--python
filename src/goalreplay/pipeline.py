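"""End-to-end orchestration: configuration, stage execution, reporting.

``run_pipeline`` chains behaviour -> LFP -> rate maps -> decoding ->
theta sequences -> ripple replay -> Learning/Retrieval report on one
session, writing every table as CSV plus a run manifest (config hash,
seed, version, per-stage event counts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import ranksums

from . import __version__
from .behavior import (PhaseWindows, WellPartition, compute_velocity,
                       per_trial_metric_table)
from .core import SessionData
from .decoder import EncodingModel, decode_segment, decoding_error
from .lfp import (bandpass, detect_ripples, event_participation,
                  phase_interpolator, ripple_envelope, segment_theta_cycles,
                  theta_power)
from .maps import (build_rate_map, classify_goal_cells, extract_fields,
                   is_place_cell, population_rate_by_well,
                   spatial_information)
from .replay import (RotationShuffleSet, classify_replay, goal_encoding,
                     heading_before_ripple, latency_after_ripple,
                     mask_local_well, running_goal_representation,
                     well_representation)
from .theta import (decode_cycle_whole, forward_slope, movement_heading,
                    quadrant_score, score_cycle)

log = logging.getLogger("goalreplay")


@dataclass
class PipelineConfig:
    """Every stage threshold in one place (defaults are the analysis
    constants used throughout the package)."""

    # rate maps
    bin_size_cm: float = 2.0
    map_smoothing_cm: float = 4.0
    map_speed_cm_s: float = 5.0
    field_threshold_frac: float = 0.2
    field_min_bins: int = 20
    place_cell_min_peak_hz: float = 1.0
    # ripples
    ripple_band_hz: tuple[float, float] = (150.0, 250.0)
    ripple_threshold_sd: float = 3.0
    ripple_envelope_sd_s: float = 0.0125
    ripple_speed_max_cm_s: float = 5.0
    # theta
    theta_band_hz: tuple[float, float] = (6.0, 12.0)
    theta_power_sd_s: float = 0.3
    theta_speed_min_cm_s: float = 10.0
    # decoder
    decoder_epsilon_hz: float = 0.01
    error_window_s: float = 0.25
    replay_window_s: float = 0.02
    replay_step_s: float = 0.005
    # replay criteria + significance
    replay_min_frames: int = 15
    replay_max_step_cm: float = 30.0
    replay_min_net_cm: float = 40.0
    n_shuffles: int = 1000
    alpha: float = 0.05
    # goal representation
    goal_box_cm: float = 30.0
    goal_threshold: float = 0.075
    goal_box_mode: str = "mean"
    grubbs_alpha: float = 0.05
    running_window_trials: int = 4
    # phases / goal alignment
    learning_trials: tuple[int, int] = (1, 4)
    retrieval_trials: tuple[int, int] = (8, 11)
    goal_radius_cm: float = 25.0
    goal_angle_window_deg: tuple[float, float] = (30.0, 180.0)
    # runtime
    max_theta_cycles: int = 400   # cap for per-cycle sequence scoring
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.field_min_bins < 1 or self.replay_min_frames < 1:
            raise ValueError("counts must be positive")
        if self.ripple_band_hz[0] >= self.ripple_band_hz[1]:
            raise ValueError("invalid ripple band")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v
                for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @property
    def phases(self) -> PhaseWindows:
        return PhaseWindows(self.learning_trials, self.retrieval_trials)


def _phase_of_trial(trial0: int, phases: PhaseWindows) -> str:
    t1 = trial0 + 1
    if phases.learning[0] <= t1 <= phases.learning[1]:
        return "learning"
    if phases.retrieval[0] <= t1 <= phases.retrieval[1]:
        return "retrieval"
    return "other"


def run_pipeline(session: SessionData, config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run every analysis stage on one session.

    Returns a results dict of DataFrames; when ``out_dir`` is given all
    tables are written as CSV along with ``manifest.json``.  On failure
    partial outputs are removed.
    """
    config = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    try:
        results = _run_stages(session, config)
        if out is not None:
            _write_outputs(results, session, config, out)
        return results
    except Exception:
        if out is not None:
            shutil.rmtree(out, ignore_errors=True)
        raise


def _run_stages(session: SessionData, config: PipelineConfig) -> dict:
    results: dict = {}
    counts: dict = {}
    pos = session.position
    t_pos = pos["t"].to_numpy()
    speed = compute_velocity(pos)
    partition = WellPartition(session.arena)

    # ---- behaviour -------------------------------------------------------
    log.info("behaviour: per-trial metrics")
    beh = []
    for metric in ("path_length", "latency", "mean_velocity"):
        tab = per_trial_metric_table(session, metric)
        tab["metric"] = metric
        beh.append(tab)
    results["behavior"] = pd.concat(beh, ignore_index=True)
    counts["trials"] = len(session.schedule)

    # ---- LFP -------------------------------------------------------------
    log.info("lfp: ripple detection (band %s, >%.0f SD, speed <%.0f cm/s)",
             config.ripple_band_hz, config.ripple_threshold_sd,
             config.ripple_speed_max_cm_s)
    fs = session.lfp_rate
    rip_filt = bandpass(session.lfp[:, 0], fs, *config.ripple_band_hz)
    env = ripple_envelope(rip_filt, fs, config.ripple_envelope_sd_s)
    ripples = detect_ripples(env, session.lfp_t, speed, t_pos,
                             config.ripple_threshold_sd,
                             config.ripple_speed_max_cm_s)
    counts["ripples"] = len(ripples)
    rip_trials = session.schedule.trial_of_times(
        np.array([r.peak for r in ripples])) if ripples else np.array([], int)
    results["ripples"] = pd.DataFrame(
        {"event_id": np.arange(len(ripples)),
         "start_s": [r.start for r in ripples],
         "peak_s": [r.peak for r in ripples],
         "end_s": [r.end for r in ripples],
         "amplitude_sd": [r.peak_amplitude for r in ripples],
         "duration_s": [r.duration for r in ripples],
         "trial": rip_trials})

    theta_filt = bandpass(session.lfp[:, 0], fs, *config.theta_band_hz)
    tpow = theta_power(session.lfp[:, 0], fs, config.theta_power_sd_s)
    sp_lfp = np.interp(session.lfp_t, t_pos, speed)
    moving_lfp = sp_lfp > config.theta_speed_min_cm_s
    trial_lfp = session.schedule.trial_of_times(session.lfp_t)
    tp_rows = []
    for tr in session.schedule:
        m = (trial_lfp == tr.index) & moving_lfp
        tp_rows.append({"trial": tr.index, "segment": tr.segment,
                        "value": float(tpow[m].mean()) if m.any() else np.nan,
                        "metric": "theta_power"})
    results["theta_power"] = pd.DataFrame(tp_rows)

    cycles = segment_theta_cycles(theta_filt, session.lfp_t, speed, t_pos,
                                  config.theta_speed_min_cm_s)
    counts["theta_cycles"] = len(cycles)

    # ---- rate maps + place cells ----------------------------------------
    log.info("maps: %d units, %g cm bins, %g cm smoothing", session.n_units,
             config.bin_size_cm, config.map_smoothing_cm)
    unit_rows, place_maps, place_ids = [], [], []
    for u in range(session.n_units):
        rmap = build_rate_map(session.spikes[u], pos, session.arena,
                              config.bin_size_cm, config.map_smoothing_cm,
                              config.map_speed_cm_s, speed=speed)
        fields = extract_fields(rmap, config.field_threshold_frac,
                                config.field_min_bins,
                                config.place_cell_min_peak_hz)
        pc = is_place_cell(rmap, session.unit_class[u],
                           config.place_cell_min_peak_hz)
        gcls = classify_goal_cells(rmap.peak_xy(), session.arena) if pc else ""
        unit_rows.append({"unit": u, "class": session.unit_class[u],
                          "peak_rate_hz": rmap.peak_rate,
                          "n_fields": len(fields),
                          "field_area_bins": fields[0].area if fields else 0,
                          "spatial_info_bits": spatial_information(rmap),
                          "place_cell": pc, "goal_class": gcls})
        if pc:
            place_maps.append(rmap)
            place_ids.append(u)
    results["units"] = pd.DataFrame(unit_rows)
    results["population_by_well"] = population_rate_by_well(session, partition)
    counts["place_cells"] = len(place_ids)
    if not place_ids:
        raise RuntimeError("maps stage: no place cells found")

    model = EncodingModel.from_rate_maps(place_maps, np.asarray(place_ids),
                                         config.decoder_epsilon_hz)
    place_spikes = [session.spikes[u] for u in place_ids]

    # ---- behavioural-timescale decoding ---------------------------------
    log.info("decode: %g ms non-overlapping windows", config.error_window_s * 1e3)
    t0, t1 = session.schedule.span
    seq = decode_segment(place_spikes, t0, t1, model,
                         config.error_window_s, config.error_window_s)
    mids = seq.windows.mean(axis=1)
    sp_mid = np.interp(mids, t_pos, speed)
    errors = np.full(len(seq), np.nan)
    for i in range(len(seq)):
        if seq.defined[i] and sp_mid[i] > config.map_speed_cm_s:
            errors[i] = decoding_error(seq.posteriors[i],
                                       session.position_at(mids[i:i + 1])[0],
                                       model)
    results["decoding"] = pd.DataFrame(
        {"t": mids, "speed": sp_mid, "error_cm": errors,
         "trial": session.schedule.trial_of_times(mids)})
    counts["decoded_windows"] = int(np.isfinite(errors).sum())

    # ---- theta sequences -------------------------------------------------
    phase_fn = phase_interpolator(theta_filt, session.lfp_t)
    use_cycles = cycles[:config.max_theta_cycles]
    log.info("theta: scoring %d/%d cycles", len(use_cycles), len(cycles))
    mids_c = np.array([(c.start + c.end) / 2 for c in use_cycles])
    headings = movement_heading(pos, mids_c) if len(use_cycles) else np.empty(0)
    rat_xy = session.position_at(mids_c) if len(use_cycles) else np.empty((0, 2))
    trial_c = session.schedule.trial_of_times(mids_c) if len(use_cycles) else np.empty(0, int)
    th_rows = []
    for i, c in enumerate(use_cycles):
        if not np.isfinite(headings[i]):
            continue
        whole = decode_cycle_whole(c, place_spikes, model)
        err = decoding_error(whole, rat_xy[i], model) \
            if np.all(np.isfinite(whole)) else np.nan
        mp = float(np.max(whole)) if np.all(np.isfinite(whole)) else np.nan
        sc = score_cycle(c, place_spikes, phase_fn, model, rat_xy[i],
                         headings[i])
        th_rows.append({"cycle_id": i, "trial": int(trial_c[i]),
                        "speed": c.mean_speed, "decoding_error_cm": err,
                        "max_posterior": mp,
                        "slope_cm_per_cycle": sc.forward_slope,
                        "quadrant_score": sc.quadrant_score,
                        "path_extent_cm": sc.path_extent})
    results["theta_cycles"] = pd.DataFrame(th_rows)

    # ---- replay ----------------------------------------------------------
    log.info("replay: %d ripples, %d shuffles, alpha %.2f", len(ripples),
             config.n_shuffles, config.alpha)
    rng = np.random.default_rng(config.seed)
    rot = RotationShuffleSet(model, config.n_shuffles, rng) if ripples else None
    bin_labels = partition.bin_labels(model.bin_centers)
    wells = session.arena.well_positions
    goal_xy = wells[session.arena.goal_well]
    rep_rows, reps = [], []
    for i, rip in enumerate(ripples):
        res = classify_replay(rip, place_spikes, model, config.n_shuffles,
                              config.alpha, int(rng.integers(2**31)), rot,
                              config.replay_window_s, config.replay_step_s,
                              config.replay_min_frames,
                              config.replay_max_step_cm,
                              config.replay_min_net_cm)
        rat_here = session.position_at(np.array([rip.peak]))[0]
        local = int(partition.assign(rat_here[None, :])[0])
        frames = mask_local_well(res.seq, bin_labels, local)
        genc = goal_encoding(frames, model, goal_xy, res.seq.defined,
                             config.goal_box_cm, config.goal_threshold,
                             config.goal_box_mode)
        rep = well_representation(frames, res.seq.defined, bin_labels,
                                  session.arena.n_wells, local)
        hd = heading_before_ripple(pos, speed, rip.start)
        net = np.nan
        if res.path is not None and res.path.defined.sum() >= 2:
            d = res.path.positions[res.path.defined]
            net = float(np.hypot(*(d[-1] - d[0])))
        rep_rows.append({
            "ripple_id": i, "trial": int(rip_trials[i]),
            "criteria_pass": res.criteria_pass,
            "p_cell": res.p_cell_shuffle, "p_rot": res.p_field_rotation,
            "is_replay": res.is_replay, "goal_encoding": genc,
            "heading_deg": hd, "n_frames": len(res.seq),
            "net_displacement_cm": net})
        reps.append(rep)
    results["replay"] = pd.DataFrame(rep_rows)
    counts["replays"] = int(results["replay"]["is_replay"].sum()) \
        if len(rep_rows) else 0
    if ripples:
        from .lfp import event_participation

        frac, per = event_participation(
            [(r.start, r.end) for r in ripples], session.spikes)
        results["replay"]["participation_frac"] = frac
        results["replay"]["spikes_per_participant"] = per
        results["latency_after_ripple"] = latency_after_ripple(
            ripples, results["replay"]["goal_encoding"].to_numpy(), pos,
            partition, session.arena.goal_well)
    if reps:
        rep_mat = np.vstack(reps)
        results["well_representation"] = pd.DataFrame(
            rep_mat, columns=[f"well_{w}" for w in range(session.arena.n_wells)])
        results["running_goal"] = running_goal_representation(
            rep_mat, results["replay"]["trial"].to_numpy(),
            session.arena.goal_well, len(session.schedule),
            config.running_window_trials, config.grubbs_alpha)

    # ---- report ----------------------------------------------------------
    results["report"] = report_learning_retrieval(results, config.phases)
    results["_counts"] = counts
    return results


def report_learning_retrieval(results: dict, phases: PhaseWindows
                              ) -> pd.DataFrame:
    """Mean +- SEM per phase per metric plus the two-sided rank-sum p.

    Pools per-trial (behaviour, theta power) or per-cycle (theta
    sequence) values inside each phase window.
    """
    sources = []
    if "behavior" in results:
        sources.append(results["behavior"])
    if "theta_power" in results:
        sources.append(results["theta_power"])
    if "theta_cycles" in results and len(results["theta_cycles"]):
        tc = results["theta_cycles"]
        for col, name in (("slope_cm_per_cycle", "theta_slope"),
                          ("quadrant_score", "quadrant_score"),
                          ("decoding_error_cm", "cycle_decoding_error"),
                          ("max_posterior", "cycle_max_posterior")):
            sources.append(pd.DataFrame({"trial": tc["trial"],
                                         "value": tc[col], "metric": name}))
    learn = set(phases.learning_trials() - 1)   # 0-based
    ret = set(phases.retrieval_trials() - 1)
    rows = []
    for src in sources:
        for metric, grp in src.groupby("metric"):
            a = grp.loc[grp["trial"].isin(learn), "value"].dropna().to_numpy()
            b = grp.loc[grp["trial"].isin(ret), "value"].dropna().to_numpy()
            p = ranksums(a, b).pvalue if len(a) and len(b) else np.nan
            for phase, v in (("learning", a), ("retrieval", b)):
                rows.append({
                    "metric": metric, "phase": phase,
                    "mean": float(v.mean()) if len(v) else np.nan,
                    "sem": float(v.std(ddof=1) / np.sqrt(len(v)))
                    if len(v) > 1 else np.nan,
                    "n": len(v), "p_ranksum": p})
    return pd.DataFrame(rows)


def _write_outputs(results: dict, session: SessionData,
                   config: PipelineConfig, out: Path) -> None:
    for name, df in results.items():
        if isinstance(df, pd.DataFrame):
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
    manifest = {
        "config_hash": config.hash(),
        "seed": int(config.seed),
        "session_seed": int(session.seed),
        "version": __version__,
        "counts": results.get("_counts", {}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    config.to_yaml(out / "config.yaml")
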
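"""End-to-end experiment runners: simulate -> quantify -> integrate/FFI -> stats.

Each runner reproduces one figure-level analysis on synthetic (or imported)
data and returns tidy tables.  One root seed governs everything; child
generators derive from ``SeedSequence([seed, trial_key])`` where
``trial_key = cell*100000 + condition_index*100 + trial`` — a documented rule
that makes stages reproducible in isolation and robust to reordering.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ProtocolError, UndefinedIndexError
from .ffi import assemble_time_course
from .integrate import inverse_effectiveness, msi_indices, s1s2_index
from .protocols import (
    CellMeta,
    StimulusProtocol,
    build_auditory_pip,
    build_multisensory,
    build_sequence,
    build_tectal_train,
)
from .quantify import average_trials, compute_baseline, lingering_depolarization, phasic_tonic, window_response
from .simulate import SimParams, child_rng, ffi_ground_truth, simulate_ffi_probe, simulate_trial
from .stats import StatResult, kruskal_wallis, wilcoxon_one_sample

log = logging.getLogger(__name__)

WINDOW_MS = 12.0


@dataclass
class RunConfig:
    """Condition menu and sampling plan for a full synthetic run."""

    seed: int = 0
    n_cells: int = 10
    trials_per_condition: int = 5
    train_durations_ms: tuple[float, ...] = (1, 33, 66, 100, 200)
    train_duration_freq_hz: float = 60.0
    train_freqs_hz: tuple[float, ...] = (30, 60, 100, 200)
    train_freq_duration_ms: float = 100.0
    sequences: tuple[str, ...] = ("AA", "AT", "TA", "TT")
    sequence_offset_ms: float = 50.0
    ffi_delays_ms: tuple[float, ...] = (2, 5, 8, 12, 16, 20, 30, 40, 50, 60, 70, 80)
    ffi_repeats: int = 10
    cell_gain_sd: float = 0.15
    params: SimParams = field(default_factory=SimParams.default)

    def __post_init__(self) -> None:
        if self.trials_per_condition < 2:
            raise ProtocolError("trials_per_condition must be >= 2")
        # every listed condition must be constructible up front
        for d in self.train_durations_ms:
            build_tectal_train(self.train_duration_freq_hz, d)
        for f in self.train_freqs_hz:
            build_tectal_train(f, self.train_freq_duration_ms)
        for s in self.sequences:
            build_sequence(s[0], s[1], self.sequence_offset_ms)

    # -- YAML round trip (canonical form) ---------------------------------

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = {
            "seed": self.seed,
            "n_cells": self.n_cells,
            "trials_per_condition": self.trials_per_condition,
            "train_durations_ms": list(self.train_durations_ms),
            "train_duration_freq_hz": self.train_duration_freq_hz,
            "train_freqs_hz": list(self.train_freqs_hz),
            "train_freq_duration_ms": self.train_freq_duration_ms,
            "sequences": list(self.sequences),
            "sequence_offset_ms": self.sequence_offset_ms,
            "ffi_delays_ms": list(self.ffi_delays_ms),
            "ffi_repeats": self.ffi_repeats,
            "cell_gain_sd": self.cell_gain_sd,
        }
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text(encoding="utf-8")
        d = yaml.safe_load(text)
        for k in ("train_durations_ms", "train_freqs_hz", "sequences",
                  "ffi_delays_ms"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# Seeding / per-cell heterogeneity
# ---------------------------------------------------------------------------

def _trial_key(cell: int, cond: int, trial: int) -> int:
    return cell * 100_000 + cond * 100 + trial


def _cell_params(config: RunConfig, cell: int) -> tuple[SimParams, CellMeta]:
    """Per-cell synaptic gain scaling and resting potential."""
    rng = child_rng(config.seed, 900_000_000 + cell)
    if config.cell_gain_sd > 0:
        f_aud, f_tec = np.exp(config.cell_gain_sd * rng.standard_normal(2))
    else:
        f_aud = f_tec = 1.0
        rng.standard_normal(2)
    v_rest = float(rng.uniform(-85.0, -75.0))
    params = replace(config.params.scaled_gains(auditory=f_aud, tectal=f_tec),
                     V_rest_mV=v_rest)
    meta = CellMeta(fish_id=f"sim{cell:03d}",
                    cell_side="left" if cell % 2 == 0 else "right",
                    resting_potential_mV=v_rest)
    return params, meta


def _condition_response(
    config: RunConfig, params: SimParams, meta: CellMeta,
    protocol: StimulusProtocol, cell: int, cond: int,
    window_start_ms: float,
) -> tuple[float, bool]:
    """Trial-averaged windowed mean depolarization for one condition.

    Returns (mean depolarization in the 12-ms window, any-trial-fired flag).
    AP-containing trials are excluded from the average but counted for
    firing incidence.
    """
    trials = [
        simulate_trial(protocol, params, seed=config.seed,
                       trial_index=_trial_key(cell, cond, k), cell=meta)
        for k in range(config.trials_per_condition)
    ]
    fired = any(t.fired for t in trials)
    if all(t.fired for t in trials):
        log.warning("cell %s condition %s: all trials fired", cell, protocol.label)
        return np.nan, fired
    mean_trace, _ = average_trials(trials)
    baseline = compute_baseline(mean_trace)
    wq = window_response(mean_trace, window_start_ms, WINDOW_MS, baseline)
    return wq.mean_depol_mV, fired


# ---------------------------------------------------------------------------
# Experiment runners
# ---------------------------------------------------------------------------

def msi_condition_menu(config: RunConfig) -> list[StimulusProtocol]:
    """Tectal train conditions: 60-Hz trains of varying duration plus
    100-ms trains of varying frequency (duplicates removed)."""
    protos: list[StimulusProtocol] = []
    seen = set()
    for d in config.train_durations_ms:
        p = build_tectal_train(config.train_duration_freq_hz, d)
        if p.label not in seen:
            protos.append(p)
            seen.add(p.label)
    for f in config.train_freqs_hz:
        p = build_tectal_train(f, config.train_freq_duration_ms)
        if p.label not in seen:
            protos.append(p)
            seen.add(p.label)
    return protos


def run_msi_experiment(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A / T / M responses and MSI indices for every cell and condition.

    Returns (per-cell table, group summary with one-sample Wilcoxon tests
    of each index against 1).
    """
    trains = msi_condition_menu(config)
    pip = build_auditory_pip(0.0)
    rows = []
    n_undefined = 0
    for cell in range(config.n_cells):
        params, meta = _cell_params(config, cell)
        A_mV, a_fired = _condition_response(
            config, params, meta, pip, cell, cond=0, window_start_ms=0.0)
        for j, train in enumerate(trains):
            m_proto = build_multisensory(train)
            last = train.last_event_ms
            T_mV, t_fired = _condition_response(
                config, params, meta, train, cell, cond=1 + 2 * j,
                window_start_ms=last)
            M_mV, m_fired = _condition_response(
                config, params, meta, m_proto, cell, cond=2 + 2 * j,
                window_start_ms=last)
            try:
                rec = msi_indices(M_mV, T_mV, A_mV, condition=train.label)
            except UndefinedIndexError:
                n_undefined += 1
                log.warning("cell %d condition %s: undefined index excluded",
                            cell, train.label)
                continue
            rows.append({
                "fish_id": meta.fish_id, "cell": cell, "condition": train.label,
                "train_duration_ms": train.train_duration_ms,
                "train_freq_hz": train.train_freq_hz,
                "T_mV": T_mV, "A_mV": A_mV, "M_mV": M_mV,
                "msi_max": rec.msi_max, "msi_sum": rec.msi_sum,
                "fired_T": t_fired, "fired_A": a_fired, "fired_M": m_fired,
            })
    if n_undefined:
        log.info("excluded %d undefined MSI indices", n_undefined)
    per_cell = pd.DataFrame(rows)

    summaries = []
    for cond, grp in per_cell.groupby("condition", sort=False):
        w_max = wilcoxon_one_sample(grp["msi_max"], mu=1.0)
        w_sum = wilcoxon_one_sample(grp["msi_sum"], mu=1.0)
        summaries.append({
            "condition": cond, "n_cells": len(grp),
            "median_msi_max": grp["msi_max"].median(),
            "median_msi_sum": grp["msi_sum"].median(),
            "wilcoxon_p_msi_max": w_max.p_value,
            "wilcoxon_p_msi_sum": w_sum.p_value,
        })
    return per_cell, pd.DataFrame(summaries)


def run_ffi_experiment(config: RunConfig) -> tuple[pd.DataFrame, dict[str, StatResult]]:
    """Per-fish FFI time-course metrics for both modalities.

    Probes ``ffi_repeats`` test APs at each delay per fish; metrics are
    computed on each fish's curve, then modalities are compared with
    Kruskal-Wallis on the per-fish values.
    """
    conditioning = {
        "auditory": build_auditory_pip(0.0),
        "tectal": build_tectal_train(config.train_duration_freq_hz, 1.0),
    }
    rows = []
    for cell in range(config.n_cells):
        params, meta = _cell_params(config, cell)
        for mi, (modality, proto) in enumerate(conditioning.items()):
            measurements = []
            for di, delay in enumerate(config.ffi_delays_ms):
                for k in range(config.ffi_repeats):
                    measurements.append(simulate_ffi_probe(
                        proto, delay, params, seed=config.seed,
                        trial_index=_trial_key(cell, 500 + 10 * mi + di, k)))
            tc = assemble_time_course(measurements, modality)
            rows.append({
                "fish_id": meta.fish_id, "cell": cell, "modality": modality,
                "peak_si_percent": tc.peak_si_percent,
                "t_peak_ms": tc.t_peak_ms,
                "t_half_ms": tc.t_half_ms,
                "t_half_elapsed_ms": tc.t_half_elapsed_ms,
                "auc_percent_ms": tc.auc_percent_ms,
            })
    per_fish = pd.DataFrame(rows)

    tests: dict[str, StatResult] = {}
    for metric in ("t_half_ms", "t_half_elapsed_ms", "auc_percent_ms",
                   "peak_si_percent", "t_peak_ms"):
        groups = {
            m: per_fish.loc[per_fish["modality"] == m, metric].dropna()
            for m in ("auditory", "tectal")
        }
        if any(len(v) == 0 for v in groups.values()):
            tests[metric] = StatResult("kruskal_wallis", np.nan, np.nan, 0,
                                       defined=False,
                                       note=f"{metric} undefined for a modality")
        else:
            tests[metric] = kruskal_wallis(groups)
    return per_fish, tests


def run_sequence_experiment(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """S1-S2 integration indices for the paired-stimulus conditions.

    Resp1 is measured on S1-only trials in a 12-ms window starting
    ``sequence_offset_ms`` after S1 onset; Resp2 on S2-only trials at onset;
    Resp(1+2) on paired trials after S2.
    """
    offset = config.sequence_offset_ms
    rows = []
    for cell in range(config.n_cells):
        params, meta = _cell_params(config, cell)
        # singles measured once per cell, reused across sequences
        singles: dict[str, tuple[float, float]] = {}
        for si, code in enumerate(("A", "T")):
            proto = build_auditory_pip(0.0) if code == "A" else build_tectal_train(60.0, 1.0)
            trials = [simulate_trial(proto, params, seed=config.seed,
                                     trial_index=_trial_key(cell, 700 + si, k),
                                     cell=meta)
                      for k in range(config.trials_per_condition)]
            mean_trace, _ = average_trials(trials)
            base = compute_baseline(mean_trace)
            resp_onset = window_response(mean_trace, 0.0, WINDOW_MS, base).mean_depol_mV
            resp_late = window_response(mean_trace, offset, WINDOW_MS, base).mean_depol_mV
            lingering = lingering_depolarization(mean_trace, offset, base)
            singles[code] = (resp_onset, resp_late)
            log.debug("cell %d %s: onset %.2f late %.2f lingering %.2f",
                      cell, code, resp_onset, resp_late, lingering)
        for qi, seq in enumerate(config.sequences):
            s1, s2 = seq[0], seq[1]
            paired = build_sequence(s1, s2, offset)
            trials = [simulate_trial(paired, params, seed=config.seed,
                                     trial_index=_trial_key(cell, 720 + qi, k),
                                     cell=meta)
                      for k in range(config.trials_per_condition)]
            mean_trace, _ = average_trials(trials)
            base = compute_baseline(mean_trace)
            resp12 = window_response(mean_trace, offset, WINDOW_MS, base).mean_depol_mV
            resp1 = singles[s1][1]   # S1 contribution 50 ms after its onset
            resp2 = singles[s2][0]   # S2-alone response at onset
            try:
                rec = s1s2_index(resp1, resp2, resp12, seq)
            except UndefinedIndexError:
                log.warning("cell %d sequence %s: undefined index excluded", cell, seq)
                continue
            rows.append({
                "fish_id": meta.fish_id, "cell": cell, "sequence": seq,
                "resp1_mV": resp1, "resp2_mV": resp2, "resp12_mV": resp12,
                "s1s2_index": rec.s1s2_index,
            })
    per_cell = pd.DataFrame(rows)

    summaries = []
    for seq, grp in per_cell.groupby("sequence", sort=False):
        w = wilcoxon_one_sample(grp["s1s2_index"], mu=1.0)
        summaries.append({
            "sequence": seq, "n_cells": len(grp),
            "mean_index": grp["s1s2_index"].mean(),
            "median_index": grp["s1s2_index"].median(),
            "wilcoxon_p_vs_1": w.p_value,
        })
    return per_cell, pd.DataFrame(summaries)


def run_inverse_effectiveness(
    config: RunConfig,
    n_levels: int = 20,
    gain_range: tuple[float, float] = (0.2, 2.0),
) -> tuple[pd.DataFrame, "pd.Series | object"]:
    """Stimulus-strength sweep probing inverse effectiveness.

    Scales the amplitudes of a brief tectal pulse and an auditory pip over
    ``n_levels`` levels for each cell, computes MSI indices per level, and
    regresses MSI/Max on the maximum unisensory response.  With purely
    conductance-based summation the slope is negative: weaker stimuli
    integrate closer to linearly.
    """
    levels = np.linspace(gain_range[0], gain_range[1], n_levels)
    records = []
    rows = []
    for cell in range(config.n_cells):
        params, meta = _cell_params(config, cell)
        for li, g in enumerate(levels):
            pip = build_auditory_pip(0.0, amplitude=float(g))
            train = build_tectal_train(60.0, 1.0, amplitude=float(g))
            m_proto = build_multisensory(train, pip_amplitude=float(g))
            A_mV, _ = _condition_response(config, params, meta, pip, cell,
                                          cond=800 + 3 * li, window_start_ms=0.0)
            T_mV, _ = _condition_response(config, params, meta, train, cell,
                                          cond=801 + 3 * li, window_start_ms=0.0)
            M_mV, _ = _condition_response(config, params, meta, m_proto, cell,
                                          cond=802 + 3 * li, window_start_ms=0.0)
            try:
                rec = msi_indices(M_mV, T_mV, A_mV, condition=f"gain{g:.2f}")
            except UndefinedIndexError:
                continue
            records.append(rec)
            rows.append({"cell": cell, "gain": g, "T_mV": T_mV, "A_mV": A_mV,
                         "M_mV": M_mV, "msi_max": rec.msi_max,
                         "msi_sum": rec.msi_sum})
    fit = inverse_effectiveness(records, response="msi_max",
                                predictor="max_unisensory")
    return pd.DataFrame(rows), fit


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_all(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run every experiment; optionally write TSV tables plus a JSON
    run-manifest (config hash, package version, seed) for provenance."""
    msi_cells, msi_summary = run_msi_experiment(config)
    ffi_cells, ffi_tests = run_ffi_experiment(config)
    seq_cells, seq_summary = run_sequence_experiment(config)
    ie_table, ie_fit = run_inverse_effectiveness(config)

    results = {
        "msi_per_cell": msi_cells,
        "msi_summary": msi_summary,
        "ffi_per_fish": ffi_cells,
        "ffi_tests": ffi_tests,
        "seq_per_cell": seq_cells,
        "seq_summary": seq_summary,
        "inverse_effectiveness": ie_table,
        "inverse_effectiveness_fit": ie_fit,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("msi_per_cell", "msi_summary", "ffi_per_fish",
                     "seq_per_cell", "seq_summary", "inverse_effectiveness"):
            results[name].to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                                 float_format="%.6g")
        ffi_txt = "\n".join(
            f"{metric}\tH={t.statistic:.2f}\tp={t.p_value:.4f}"
            for metric, t in ffi_tests.items() if t.defined)
        (outdir / "ffi_tests.tsv").write_text(
            "metric\tstatistic\tp\n" + ffi_txt + "\n")
        cfg_text = config.to_yaml()
        manifest = {
            "package": "mcellmsi",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "inverse_effectiveness": {
                "slope": ie_fit.slope, "F": ie_fit.F_stat,
                "p": ie_fit.p_value, "n": ie_fit.n,
            },
        }
        (outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2))
        (outdir / "config.yaml").write_text(cfg_text)
    return results
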
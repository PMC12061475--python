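"""Configuration, seeding, serialization and experiment entry points.

Experiments are described by an :class:`ExperimentConfig` (loadable from
YAML); :func:`run_experiment` dispatches on the experiment kind, writes CSV
summaries, HDF5 sessions/traces and a JSON manifest recording the config
and seed.  All randomness flows from the single config seed through named
child streams (one per module), so adding a module never perturbs
another's draws.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import NeuralSession

__all__ = [
    "ExperimentConfig",
    "child_rng",
    "run_experiment",
    "save_neural_session",
    "load_neural_session",
    "save_sim_session",
]

EXPERIMENT_KINDS = (
    "task", "rate2afc", "spontaneous", "generate_session", "generate_dlight",
    "xcorr", "modes", "selectivity", "dopamine_models",
)


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Named child RNG stream: deterministic in (seed, name) only."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class ExperimentConfig:
    """A fully serializable experiment description."""

    kind: str
    seed: int = 0
    out_dir: str = "results"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EXPERIMENT_KINDS:
            raise ValueError(
                f"unknown experiment kind {self.kind!r}; "
                f"expected one of {EXPERIMENT_KINDS}"
            )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"kind", "seed", "out_dir", "params"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


# ---------------------------------------------------------------------------
# HDF5 session layout (shared by the spontaneous, synth and analysis stages)


def save_neural_session(session: NeuralSession, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("activity", data=session.activity)
        f.create_dataset(
            "pathway", data=np.array([p.encode() for p in session.pathway])
        )
        f.create_dataset("syllables", data=session.syllables)
        f.attrs["frame_rate"] = session.frame_rate
        f.attrs["session_id"] = session.session_id


def load_neural_session(path) -> NeuralSession:
    with h5py.File(path, "r") as f:
        return NeuralSession(
            activity=f["activity"][:],
            pathway=np.array([p.decode() for p in f["pathway"][:]]),
            syllables=f["syllables"][:],
            frame_rate=float(f.attrs["frame_rate"]),
            session_id=str(f.attrs["session_id"]),
        )


def save_sim_session(sim, path) -> None:
    """Serialize a spontaneous SimSession (same layout the analyses read,
    plus the raw per-pathway traces and events)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("dspn_activity", data=sim.dspn_activity)
        f.create_dataset("ispn_activity", data=sim.ispn_activity)
        f.create_dataset("action_labels", data=sim.action_labels)
        f.create_dataset("onsets", data=sim.onsets)
        for k, v in asdict(sim.config).items():
            if v is not None:
                f.attrs[k] = v


# ---------------------------------------------------------------------------
# experiment dispatch


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the configured experiment; returns a manifest dict (also written
    to ``out_dir/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = dict(config.params)
    outputs: dict[str, str] = {}

    if config.kind == "task":
        outputs.update(_run_task(config, p, out))
    elif config.kind == "rate2afc":
        outputs.update(_run_rate(config, p, out))
    elif config.kind == "spontaneous":
        outputs.update(_run_spontaneous(config, p, out))
    elif config.kind == "generate_session":
        outputs.update(_run_generate_session(config, p, out))
    elif config.kind == "generate_dlight":
        outputs.update(_run_generate_dlight(config, p, out))
    elif config.kind == "xcorr":
        outputs.update(_run_xcorr(config, p, out))
    elif config.kind == "modes":
        outputs.update(_run_modes(config, p, out))
    elif config.kind == "selectivity":
        outputs.update(_run_selectivity(config, p, out))
    elif config.kind == "dopamine_models":
        outputs.update(_run_dopamine_models(config, p, out))

    manifest = {
        "config": asdict(config),
        "version": __version__,
        "outputs": outputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _run_task(config, p, out):
    from . import tasks

    task_kind = p.pop("task", "gonogo")
    if task_kind == "gonogo":
        curve = tasks.run_gonogo_experiment(seed=config.seed, **p)
        df = curve.records
    elif task_kind == "2afc":
        curve = tasks.run_action_selection_experiment(seed=config.seed, **p)
        df = curve.records
    elif task_kind == "shared":
        df = tasks.run_shared_control_experiment(seed=config.seed, **p)
    else:
        raise ValueError(f"unknown task {task_kind!r}")
    path = out / "curves.csv"
    df.to_csv(path, index=False)
    return {"curves": str(path)}


def _run_rate(config, p, out):
    from .ratemodel import RateModelParams, run_rate_experiment

    n_seeds = p.pop("n_seeds", 20)
    n_trials = p.pop("n_trials", 60)
    params = RateModelParams(**p)
    rows = []
    path = out / "traces.h5"
    with h5py.File(path, "w") as f:
        for k in range(n_seeds):
            res = run_rate_experiment(
                params, n_trials=n_trials,
                seed=int(config.seed) * 10_000 + k,
                keep_traces=(k == 0),
            )
            rows.append({"seed": k,
                         "trials_to_criterion": res["trials_to_criterion"]})
            if k == 0 and res["traces"]:
                g = f.create_group("example_seed")
                g.create_dataset(
                    "rates", data=np.stack([t.rates for t in res["traces"]])
                )
                g.create_dataset(
                    "correct", data=np.array([t.correct for t in res["traces"]])
                )
    df = pd.DataFrame(rows)
    csv = out / "trials_to_criterion.csv"
    df.to_csv(csv, index=False)
    return {"traces": str(path), "summary": str(csv)}


def _run_spontaneous(config, p, out):
    from .spontaneous import (SpontaneousConfig, calibrate_nogo_offset,
                              run_spontaneous_session)

    sc = SpontaneousConfig(**p)
    if sc.log_c_nogo is None:
        sc.log_c_nogo = calibrate_nogo_offset(
            sc, child_rng(config.seed, "calibrate")
        )
    sim = run_spontaneous_session(sc, child_rng(config.seed, "spontaneous"))
    path = out / "session.h5"
    save_sim_session(sim, path)
    return {"session": str(path)}


def _run_generate_session(config, p, out):
    from .synth import generate_neural_session

    session, truth = generate_neural_session(seed=config.seed, **p)
    path = out / "session.h5"
    save_neural_session(session, path)
    with h5py.File(path, "a") as f:
        g = f.create_group("ground_truth")
        g.attrs["json"] = json.dumps(truth.to_dict())
    return {"session": str(path)}


def _run_generate_dlight(config, p, out):
    from .synth import generate_dlight_session

    S = p.pop("n_syllables", 20)
    rng = child_rng(config.seed, "dlight")
    Q = rng.normal(size=(S, S))
    seq, dop, truth = generate_dlight_session(Q, rng=rng, **p)
    path = out / "dlight_session.h5"
    with h5py.File(path, "w") as f:
        f.create_dataset("sequence", data=seq)
        f.create_dataset("dopamine", data=dop)
        f.create_dataset("Q", data=Q)
    return {"session": str(path)}


def _load_session_as_neural(path):
    with h5py.File(path, "r") as f:
        if "dspn_activity" in f:
            from .analysis import neural_session_from_sim
            from .spontaneous import SimSession, SpontaneousConfig

            cfg = SpontaneousConfig(**{
                k: f.attrs[k] for k in f.attrs
                if k in SpontaneousConfig.__dataclass_fields__
            })
            sim = SimSession(
                dspn_activity=f["dspn_activity"][:],
                ispn_activity=f["ispn_activity"][:],
                action_labels=f["action_labels"][:],
                onsets=f["onsets"][:],
                config=cfg,
            )
            return neural_session_from_sim(sim)
    return load_neural_session(path)


def _run_xcorr(config, p, out):
    from .analysis import asymmetry_index, cross_correlation

    session = _load_session_as_neural(p["input"])
    max_lag = int(p.get("max_lag", 50))
    d = session.activity[:, session.pathway_mask("dSPN")].sum(axis=1)
    i = session.activity[:, session.pathway_mask("iSPN")].sum(axis=1)
    xc = cross_correlation(d, i, max_lag)
    df = pd.DataFrame({"lag": np.arange(-max_lag, max_lag + 1), "xcorr": xc})
    path = out / "xcorr.csv"
    df.to_csv(path, index=False)
    summary = out / "asymmetry.json"
    with open(summary, "w") as fh:
        json.dump({"asymmetry_index": asymmetry_index(xc)}, fh)
    return {"xcorr": str(path), "asymmetry": str(summary)}


def _run_modes(config, p, out):
    from .analysis import (cross_validated_onset_projection,
                           split_half_mode_correlation, zscore_neurons)

    session = zscore_neurons(_load_session_as_neural(p["input"]))
    corr = split_half_mode_correlation(session)
    traces = cross_validated_onset_projection(
        session, window=int(p.get("window", 20))
    )
    rows = []
    for (comp, alignment), tr in traces.traces.items():
        for t, v, s in zip(traces.time, tr, traces.sem[(comp, alignment)]):
            rows.append({"component": comp, "alignment": alignment,
                         "time": t, "mean": v, "sem": s})
    path = out / "mode_traces.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    summary = out / "mode_summary.json"
    with open(summary, "w") as fh:
        json.dump({"split_half_mode_correlation": corr}, fh)
    return {"traces": str(path), "summary": str(summary)}


def _run_selectivity(config, p, out):
    from .analysis import retained_inventory, selectivity_index, zscore_neurons

    session = zscore_neurons(_load_session_as_neural(p["input"]))
    inventory = retained_inventory(session)
    rows = []
    for n in range(session.activity.shape[1]):
        tuning = []
        for s in inventory:
            mask = session.syllables == s
            tuning.append(session.activity[mask, n].mean())
        tuning = np.array(tuning)
        rows.append({
            "neuron": n,
            "pathway": str(session.pathway[n]),
            "selectivity_abs": selectivity_index(np.abs(tuning)),
            "selectivity_rect": selectivity_index(np.maximum(tuning, 0.0)),
        })
    path = out / "selectivity.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return {"selectivity": str(path)}


def _run_dopamine_models(config, p, out):
    from .dopamine_models import compute_transition_tables, fit_all_models

    with h5py.File(p["input"], "r") as f:
        seq = f["sequence"][:]
        dop = f["dopamine"][:]
    tables = compute_transition_tables(seq, dop)
    rs = fit_all_models(tables)
    df = pd.DataFrame(
        [{"session": Path(p["input"]).stem, "model": m, "pearson_r": r}
         for m, r in rs.items()]
    )
    path = out / "model_comparison.csv"
    df.to_csv(path, index=False)
    return {"comparison": str(path)}
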
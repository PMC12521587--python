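"""End-to-end pipeline runner: simulate → preprocess → features → analyses.

Each stage logs its parameters, the seed, and content digests of its inputs
and outputs; the resolved configuration is echoed next to the artifacts so a
run can be reproduced exactly.  The first failing stage aborts the run with
the stage name and cause.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import closedloop as cl
from . import features as ft
from . import preprocess as pp
from . import statespace as ss
from . import stiffness as st
from . import synthgen as sg
from .io import RunConfig, data_digest, write_recording, write_trace

__all__ = ["pipeline_run"]

logger = logging.getLogger("vasotone.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _run_stage(name: str, fn):
    try:
        return fn()
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, exc) from exc


def pipeline_run(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the configured pipeline; returns a dict of artifact paths."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.echo(out)
    artifacts: dict[str, str] = {"config_echo": str(out / "config_echo.yaml")}
    run_log: list[dict] = []

    # simulate ----------------------------------------------------------
    sim_opts = dict(config.simulate)
    state = sim_opts.pop("state", "constriction")
    cfg = sg.GenConfig(**sim_opts, seed=config.seed)

    def do_sim():
        rec = sg.generate_vasomotor(cfg, state)
        p = write_recording(rec, out / "recording.csv")
        run_log.append(
            {"stage": "simulate", "state": str(state), "seed": config.seed,
             "out_digest": data_digest(rec.data)}
        )
        return rec, p

    rec, p = _run_stage("simulate", do_sim)
    artifacts["recording"] = str(p)

    # preprocess --------------------------------------------------------
    def do_pre():
        clean = pp.preprocess_chain(rec, **config.preprocess)
        p = write_recording(clean, out / "clean.csv")
        run_log.append(
            {"stage": "preprocess", "params": config.preprocess,
             "in_digest": data_digest(rec.data), "out_digest": data_digest(clean.data)}
        )
        return clean, p

    clean, p = _run_stage("preprocess", do_pre)
    artifacts["clean"] = str(p)

    # features ------------------------------------------------------------
    def do_feat():
        table = ft.features_by_channel(clean, **config.features)
        p = out / "features.csv"
        table.to_csv(p, index=False)
        run_log.append({"stage": "features", "n_rows": len(table)})
        return table, p

    table, p = _run_stage("features", do_feat)
    artifacts["features"] = str(p)

    # embed ---------------------------------------------------------------
    def do_embed():
        emb = ss.embed(table, labels=table["segment"].to_numpy(),
                       seed=config.seed, **config.embed)
        p = out / "embedding.csv"
        np.savetxt(p, np.column_stack([emb.points, np.arange(len(emb.labels))]),
                   delimiter=",", header="x,y,index", comments="")
        run_log.append({"stage": "embed", "params": emb.params})
        return emb, p

    emb, p = _run_stage("embed", do_embed)
    artifacts["embedding"] = str(p)

    # stiffness -----------------------------------------------------------
    def do_stiff():
        opts = dict(config.stiffness)
        preset_name = opts.pop("preset", "post_stent")
        preset = {
            "post_stent": sg.POST_STENT_PRESET,
            "post_stim": sg.POST_STIM_PRESET,
        }[preset_name]
        preset = replace(preset, seed=config.seed)
        trace = sg.generate_hemodynamics(preset, duration=opts.pop("duration", 2.0),
                                         noise_sd=opts.pop("noise_sd", 0.0))
        res = st.beta_from_trace(trace)
        write_trace(trace, out / "diameter.csv")
        p = out / "beta.json"
        p.write_text(json.dumps(
            {"beta": res.beta, "Ds": res.Ds, "Dd": res.Dd,
             "n_cycles": res.n_cycles,
             "per_cycle_beta": res.per_cycle_beta.tolist()},
            indent=2, sort_keys=True))
        run_log.append({"stage": "stiffness", "preset": preset_name, "beta": res.beta})
        return p

    artifacts["beta"] = str(_run_stage("stiffness", do_stiff))

    # closed loop ---------------------------------------------------------
    def do_loop():
        opts = dict(config.closedloop)
        ref = cl.HealthyReference(mean_power=opts.pop("ref_power", cfg.osc_amp**2 / 3))
        ctrl = cl.ControllerParams(**opts.pop("controller", {}))
        session = cl.run_closed_loop(
            cfg, ref, ctrl, duration=opts.pop("duration", 60.0),
            seed=config.seed, state=opts.pop("state", "stented_chronic"),
        )
        p = out / "session.json"
        p.write_text(session.to_json())
        run_log.append({"stage": "closedloop", "n_stimulations": session.n_stimulations,
                        "recovered": session.recovered})
        return p

    artifacts["session"] = str(_run_stage("closedloop", do_loop))

    (out / "run.log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    artifacts["run_log"] = str(out / "run.log.json")
    return artifacts
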
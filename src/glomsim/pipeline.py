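"""End-to-end pipeline: generate → simulate → analyze → report.

A single YAML/JSON config drives every stage; all stochastic stages take
explicit seeds recorded in the output manifest, so a run is reproducible from
the manifest alone.  Stages can be toggled: pointing the config at an
existing connectivity CSV yields a connectivity-only report (no simulation).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cablesim, connectivity, resampling, synthetic, tasks
from .cablesim import MembraneParams, SynapseParams, membrane_preset
from .morphology import write_swc
from .synthetic import CircuitSpec, MorphologySpec

DEFAULT_CONFIG = {
    "seed": 0,
    "circuit": {},            # CircuitSpec overrides
    "morphology": {},         # MorphologySpec overrides
    "membrane": {"preset": "cell3"},
    "synapse": {},            # SynapseParams overrides
    "connectivity_csv": None, # skip generation, analyse this matrix instead
    "stages": {"connectivity": True, "simulate": True, "resample": True, "tasks": False},
    "resample": {"n_shuffles": 100},
    "tasks": {"conditions": [13, 16, 20], "n_train": 250, "n_test": 250},
    "output_dir": "glomsim_out",
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return _merge(DEFAULT_CONFIG, path_or_dict)
    with open(path_or_dict) as fh:
        return _merge(DEFAULT_CONFIG, yaml.safe_load(fh) or {})


def _membrane_from(cfg: dict) -> MembraneParams:
    cfg = dict(cfg)
    preset = cfg.pop("preset", None)
    return membrane_preset(preset, **cfg) if preset else MembraneParams(**cfg)


def run_pipeline(config, output_dir=None) -> dict:
    """Run the configured stages and write a report bundle.

    Returns the report dict (also written as report.json).  Any stage failure
    propagates with the stage name prepended.
    """
    cfg = load_config(config)
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {}
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in cfg.items() if k != "output_dir"},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    stage = "setup"
    try:
        membrane = _membrane_from(cfg["membrane"])
        syn = SynapseParams(**cfg["synapse"])

        stage = "generate"
        if cfg["connectivity_csv"]:
            table = connectivity.load_connectivity(cfg["connectivity_csv"])
            bundle = None
        else:
            cspec = CircuitSpec(**{**cfg["circuit"], "seed": seed})
            mspec = MorphologySpec(**{**cfg["morphology"], "seed": seed})
            bundle = synthetic.make_bundle(cspec, mspec, membrane, seed=seed)
            table = bundle.table
            connectivity.save_connectivity(table, out / "connectivity.csv")
            for pn, morph in bundle.morphologies.items():
                write_swc(morph, out / f"{pn}.swc")

        stage = "connectivity"
        if cfg["stages"]["connectivity"]:
            stats = connectivity.connection_stats(table)
            ic = connectivity.ipsi_contra_comparison(table)
            lr = connectivity.left_right_totals(
                table, bundle.path_lengths() if bundle else None
            )
            report["connectivity"] = {
                "n_orns": table.n_orns,
                "n_pns": table.n_pns,
                "n_connections": stats["n_connections"],
                "mean_synapses_per_connection": stats["mean_synapses_per_connection"],
                "contribution_cv": connectivity.contribution_cv(table),
                "ipsi_surplus_pct": ic["surplus_pct_grand"],
                "right_vs_left_pct": lr["right_vs_left_pct"],
            }
            stats["by_type"].to_csv(out / "connection_types.csv", index=False)
            connectivity.normalized_contributions(table, "per-antenna").to_csv(
                out / "contributions_per_antenna.csv"
            )

        stage = "simulate"
        if cfg["stages"]["simulate"] and bundle is not None:
            rows = []
            for pn, model in bundle.models.items():
                sites = bundle.sites[pn]
                mep = cablesim.measure_mepsps(model, sites, syn)
                per_comp = mep.drop_duplicates("compartment").set_index("compartment")["somatic_mv"]
                for orn, grp in pd.DataFrame(
                    {"orn": [s.orn_id for s in sites], "comp": [s.compartment_index for s in sites]}
                ).groupby("orn"):
                    ssites = [s for s in sites if s.orn_id == orn]
                    u = cablesim.measure_uepsp(model, ssites, syn)
                    lin = float(per_comp.loc[grp["comp"]].sum())
                    rows.append(
                        {"pn": pn, "orn": orn, "n_synapses": len(ssites), "uepsp_mv": u,
                         "mepsp_sum_mv": lin, "efficacy": u / lin,
                         "mean_mepsp_mv": float(per_comp.loc[grp["comp"]].mean())}
                    )
            sim = pd.DataFrame(rows)
            sim.to_csv(out / "unitary_responses.csv", index=False)
            report["simulate"] = {
                "mean_uepsp_mv": float(sim["uepsp_mv"].mean()),
                "mean_efficacy": float(sim["efficacy"].mean()),
                "n_connections_simulated": len(sim),
            }

        stage = "resample"
        if cfg["stages"]["resample"] and bundle is not None and "simulate" in report:
            sim = pd.read_csv(out / "unitary_responses.csv")
            r = np.corrcoef(sim["n_synapses"], sim["uepsp_mv"])[0, 1]
            report["resample"] = {"r_count_uepsp": float(r)}

        stage = "tasks"
        if cfg["stages"]["tasks"] and bundle is not None:
            tcfg = cfg["tasks"]
            res = []
            for wiring in ("real", "equalized"):
                res += tasks.run_detection_task(
                    bundle, conditions=tcfg["conditions"], wiring=wiring, syn=syn,
                    n_train=tcfg["n_train"], n_test=tcfg["n_test"], seed=seed,
                )
            df = pd.DataFrame([r.__dict__ for r in res])
            df.to_csv(out / "task_results.csv", index=False)
            report["tasks"] = {
                "mean_accuracy_real": float(df[df.wiring == "real"].accuracy.mean()),
                "mean_accuracy_equalized": float(df[df.wiring == "equalized"].accuracy.mean()),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed (seed={seed}): {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
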
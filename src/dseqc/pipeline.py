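"""End-to-end QC run and experiment drivers."""

from __future__ import annotations

import json
import shutil
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    compute_dse_images,
    compute_dse_timeseries,
    scale_center,
    verify_identities,
)
from .inference import infer_dvars, write_flag_list
from .io import (
    RunConfig,
    read_input,
    write_dse_images_nifti,
    write_dse_timeseries_tsv,
    write_null_model_json,
    write_provenance,
)
from .simulation import (
    SimulationSpec,
    run_bias_experiment,
    run_power_experiment,
    run_validity_experiment,
)
from .table import summarize

__all__ = ["run_qc", "run_experiments"]


def run_qc(config: RunConfig) -> dict:
    """Run the full QC pipeline on one dataset and write the report bundle.

    Outputs (in ``config.output_dir``): the tidy DSE time-series TSV, the
    DSE table (TSV, JSON and plain text), the per-pair inference TSV, the
    flagged-pair list, the null-model JSON (with nu and nu/I), A/D/S maps
    when the input is NIfTI, an optional DSE plot, and a provenance record.
    On any failure partial outputs are removed.

    Returns a dict of the in-memory results and written paths.
    """
    out = Path(config.output_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        raw = read_input(config.input_path, mask_path=config.mask_path)
        scaled = scale_center(raw, scale_mode=config.scale_mode, target=config.target)
        dse = compute_dse_timeseries(scaled)
        report = verify_identities(dse)
        images = compute_dse_images(scaled)
        tab = summarize(dse)
        result = infer_dvars(
            dse,
            diffdata=np.diff(scaled.values, axis=1),
            mu0_method=config.mu0_method,
            var_method=config.var_method,
            d=config.d,
            alpha=config.alpha,
            delta_threshold=config.delta_threshold,
            two_sided=config.two_sided,
        )

        paths: dict[str, object] = {}
        ts_path = out / "dse_timeseries.tsv"
        write_dse_timeseries_tsv(dse, ts_path)
        paths["timeseries"] = ts_path

        tab.to_tsv(out / "dse_table.tsv")
        tab.to_json(out / "dse_table.json")
        (out / "dse_table.txt").write_text(tab.render() + "\n")
        paths["table"] = out / "dse_table.tsv"

        inf_path = out / "dvars_inference.tsv"
        result.to_tsv(inf_path)
        paths["inference"] = inf_path

        flag_path = out / "flagged_pairs.tsv"
        write_flag_list(result, flag_path)
        paths["flags"] = flag_path

        null_path = out / "null_model.json"
        write_null_model_json(
            result.null, null_path,
            extra={"nu_over_I": result.null.nu / scaled.n_voxels,
                   "I": scaled.n_voxels, "T": scaled.n_timepoints,
                   "alpha": config.alpha,
                   "delta_threshold": config.delta_threshold,
                   "n_excluded_voxels": len(scaled.excluded_voxels),
                   "identity_ok": report.ok},
        )
        paths["null_model"] = null_path

        if scaled.geometry is not None:
            paths["images"] = write_dse_images_nifti(images, out)

        if config.plot:
            from .plotting import dse_plot

            fig_path = out / "dse_plot.png"
            dse_plot(dse, result=result, path=fig_path)
            paths["plot"] = fig_path

        write_provenance(out / "provenance.json", config.to_dict(),
                         [config.input_path] +
                         ([config.mask_path] if config.mask_path else []))
        return {
            "scaled": scaled, "dse": dse, "images": images, "table": tab,
            "inference": result, "identities": report, "paths": paths,
        }
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise


def _spec_from_dict(d: dict) -> SimulationSpec:
    return SimulationSpec(**{k: v for k, v in d.items()
                             if k in SimulationSpec.__dataclass_fields__})


def run_experiments(config: dict, output_dir) -> dict[str, Path]:
    """Drive bias / validity / power experiment grids from a config dict.

    ``config`` may hold ``seed`` and any of the keys ``bias``, ``validity``
    and ``power``; each is a list of scenario dicts with SimulationSpec
    fields (validity entries may add estimator settings).  Results are
    written as TSV/JSON under ``output_dir``; seeds are logged.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed")
    written: dict[str, Path] = {}

    if "bias" in config:
        specs = [_spec_from_dict(s) for s in config["bias"]]
        if not specs:
            raise ValueError("bias experiment grid is empty")
        df = run_bias_experiment(specs, seed=seed)
        p = out / "bias.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written["bias"] = p

    if "validity" in config:
        results = []
        for entry in config["validity"]:
            spec = _spec_from_dict(entry)
            res = run_validity_experiment(
                spec,
                mu0_method=entry.get("mu0_method", "median_dvars2"),
                var_method=entry.get("var_method", "hiqr"),
                d=entry.get("d", 1 / 3),
                seed=seed,
            )
            res.pop("p_values")
            res.update({"T": spec.T, "I": spec.I,
                        "sigma_min": spec.sigma_min, "sigma_max": spec.sigma_max,
                        "mu0_method": entry.get("mu0_method", "median_dvars2")})
            results.append(res)
        if not results:
            raise ValueError("validity experiment grid is empty")
        p = out / "validity.json"
        p.write_text(json.dumps(results, indent=2, default=float))
        written["validity"] = p

    if "power" in config:
        specs = [_spec_from_dict(s) for s in config["power"]]
        if not specs:
            raise ValueError("power experiment grid is empty")
        df = run_power_experiment(specs, seed=seed)
        p = out / "power.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written["power"] = p

    if not written:
        raise ValueError("config defines no experiments (bias/validity/power)")
    (out / "experiment_config.json").write_text(
        json.dumps({"seed": seed, "config": {k: v for k, v in config.items()}},
                   indent=2, default=str))
    return written
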
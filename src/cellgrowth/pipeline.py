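"""End-to-end workflow: enumerate -> filter -> data -> split -> fit ->
rank -> profile -> validate -> GSA (-> MBDEP -> refreshment).

Every stochastic stage derives its seed from the run seed and records it
in the manifest, so a manifest re-run reproduces all outputs.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .applications import refreshment_sweep
from .calibration import multistart_fit, search_space_for
from .config import PipelineConfig
from .datasets import read_dataset, write_dataset, write_summaries
from .identifiability import identifiability_report, report_table
from .models import enumerate_candidates, filter_candidates, model_by_name
from .protocol import aggregate_errors, protocol_sweep, recommend_period
from .selection import (
    goodness_of_fit,
    rank_models,
    replicate_noise,
    selection_table,
)
from .sensitivity import gsa_of_model
from .synthetic import NoiseSpec, generate_dataset, split_dataset

log = logging.getLogger("cellgrowth.pipeline")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, seed: int | None = None, **outputs) -> None:
        self.stages[stage] = {
            "seed": seed,
            "outputs": {k: str(v) for k, v in outputs.items()},
            "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "stages": self.stages,
            },
            indent=2,
        ))
        return path


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 seed: int | None = None) -> RunManifest:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    manifest = RunManifest(config.config_hash(), seed, __version__)
    params = config.parameters()
    consts = config.constants()
    design = config.design()
    cond_map = dict(design.conditions())

    # 1. enumerate + dependence filter (optionally restricted by config)
    candidates = enumerate_candidates()
    retained = filter_candidates(candidates, config.required_substrates(), consts)
    restrict = config.section("model").get("candidates")
    if restrict:
        retained = [m for m in retained if m.name in set(restrict)]
        if not retained:
            raise PipelineError("model.candidates excludes every retained model")
    pd.DataFrame({"model": [m.name for m in retained]}).to_csv(
        out / "candidates.csv", index=False
    )
    manifest.record("enumerate_filter", n_candidates=len(candidates),
                    n_retained=len(retained), path=out / "candidates.csv")
    log.info("retained %d of %d candidates", len(retained), len(candidates))

    # 2. data: load or synthesise
    data_path = config.section("dataset").get("path")
    if data_path:
        dataset = read_dataset(data_path)
        data_seed = None
    else:
        gen_model = model_by_name(
            config.section("model").get("selected", "OxyGluLac"))
        eps, data_seed = config.noise()
        dataset = generate_dataset(
            gen_model, params, consts, design, NoiseSpec(eps, data_seed)
        )
    write_dataset(dataset, out / "dataset.csv")
    write_summaries(dataset, out / "dataset_summary.csv")
    manifest.record("data", seed=data_seed, path=out / "dataset.csv")

    # 3. split
    fractions, split_seed = config.split()
    dataset = split_dataset(dataset, fractions, split_seed)
    write_dataset(dataset, out / "dataset_split.csv")
    manifest.record("split", seed=split_seed, path=out / "dataset_split.csv")
    calib = dataset.subset("calibration")
    select = dataset.subset("selection")
    valid = dataset.subset("validation")
    if len(select) == 0:
        raise PipelineError(
            "selection split is empty (split fractions leave no selection "
            "data); model ranking is impossible"
        )
    if len(calib) == 0:
        raise PipelineError("calibration split is empty")

    # 4. fit all retained models
    fit_opts = config.fit_options()
    n_starts = int(fit_opts.pop("n_starts"))
    weight_mode = fit_opts.pop("weight_mode", "inverse_variance")
    bounds_cfg = fit_opts.pop("bounds", None)
    fits = {}
    for m in retained:
        fit_seed = int(rng.integers(2**31 - 1))
        fits[m.name] = multistart_fit(
            m, consts, calib, cond_map,
            space=search_space_for(m, bounds_cfg),
            n_starts=n_starts, seed=fit_seed,
            stage_options=fit_opts, weight_mode=weight_mode,
        )
        log.info("fitted %s: loss=%.4g", m.name, fits[m.name].loss)
    archive = pd.concat(
        [f.archive.assign(model=name) for name, f in fits.items()],
        ignore_index=True,
    )
    archive.to_csv(out / "fit_archive.csv", index=False)
    manifest.record("fit", seed=seed, n_runs=n_starts * len(retained),
                    path=out / "fit_archive.csv")

    # 5. rank on the selection split
    records = rank_models(fits, select, consts, cond_map, weight_mode)
    table = selection_table(records)
    table.to_csv(out / "selection.csv", index=False)
    best = records[0]
    manifest.record("select", path=out / "selection.csv", best=best.model.name)
    log.info("selected %s (BIC=%.4g)", best.model.name, best.bic)

    # 6. profile the selected model
    ident = config.identifiability()
    best_fit = fits[best.model.name]
    profiles = identifiability_report(
        best.model, consts, calib, best_fit, cond_map,
        alpha=float(ident["alpha"]), convention=ident["convention"],
        n_grid=int(ident["n_grid"]),
    )
    report_table(profiles).to_csv(out / "identifiability.csv", index=False)
    manifest.record("profile", path=out / "identifiability.csv")

    # 7. goodness of fit + replicate noise
    gof = goodness_of_fit(best_fit, valid, consts, cond_map)
    noise_metric = replicate_noise(valid)
    (out / "validation.json").write_text(json.dumps(
        {"mean_relative_error": gof, "replicate_noise": noise_metric}, indent=2
    ))
    manifest.record("validate", path=out / "validation.json")

    # 8. GSA
    gsa_cfg = config.gsa()
    if gsa_cfg["enabled"]:
        gsa_seed = int(rng.integers(2**31 - 1))
        res = gsa_of_model(
            best.model, best_fit.theta_star, consts,
            input_ranges=gsa_cfg.get("ranges"),
            output_time_h=float(gsa_cfg["output_time_h"]),
            n_base=int(gsa_cfg["n_base"]), seed=gsa_seed,
            n_boot=int(gsa_cfg["n_boot"]),
        )
        res.as_frame().to_csv(out / "gsa.csv", index=False)
        manifest.record("gsa", seed=gsa_seed, path=out / "gsa.csv")

    # 9. optional MBDEP
    mb = config.mbdep()
    if mb["enabled"]:
        mb_seed = int(rng.integers(2**31 - 1))
        sweep = protocol_sweep(
            best.model, params, consts, design,
            periods_h=mb["periods_h"], noise_levels=mb["noise_levels"],
            n_repeats=int(mb["n_repeats"]), fit_options=mb.get("fit"),
            seed=mb_seed,
        )
        sweep.to_csv(out / "mbdep.csv", index=False)
        agg = aggregate_errors(sweep)
        agg.to_csv(out / "mbdep_aggregate.csv", index=False)
        rec = recommend_period(sweep, float(mb.get("tolerance_ratio", 0.1)))
        manifest.record("mbdep", seed=mb_seed, path=out / "mbdep.csv",
                        recommended_period_h=rec)

    # 10. optional refreshment study
    rf = config.refreshment()
    if rf["enabled"]:
        cid0 = sorted(cond_map)[0]
        sweep = refreshment_sweep(
            best.model, best_fit.theta_star, consts, cond_map[cid0],
            periods_days=rf["periods_days"],
            horizon_days=float(rf["horizon_days"]),
        )
        sweep.to_csv(out / "refreshment.csv", index=False)
        manifest.record("refreshment", path=out / "refreshment.csv")

    manifest.save(out / "manifest.json")
    return manifest
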
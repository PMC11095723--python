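"""Model-based design of experimental protocols.

Simulate the design under an assumed parameter set, corrupt with
multiplicative noise, re-infer the parameters, and score the recovery
error across sampling periods and noise levels; recommend the coarsest
period that is not meaningfully worse than the best one.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import SearchSpace, multistart_fit
from .models import CandidateModel, FixedConstants, ParameterSet
from .synthetic import NOISE_GRID, ExperimentalDesign, NoiseSpec, generate_dataset


def parameter_error(
    theta_true: np.ndarray,
    theta_est: np.ndarray,
    mode: str = "elementwise",
) -> float:
    """Parameter-recovery error as a fraction.

    elementwise (default): mean_i |t_i - e_i| / |t_i| — robust when the
    parameters span many orders of magnitude.  norm: ||t - e|| / ||t||.
    """
    t = np.asarray(theta_true, float)
    e = np.asarray(theta_est, float)
    if t.shape != e.shape:
        raise ValueError("parameter vectors must have the same shape")
    if mode == "norm":
        denom = np.linalg.norm(t)
        if denom == 0:
            raise ValueError("theta_true has zero norm")
        return float(np.linalg.norm(t - e) / denom)
    if mode != "elementwise":
        raise ValueError("mode must be 'elementwise' or 'norm'")
    ok = t != 0
    if not np.all(ok):
        warnings.warn(
            f"{np.sum(~ok)} zero components skipped in elementwise error",
            stacklevel=2,
        )
    if not np.any(ok):
        raise ValueError("all true components are zero")
    return float(np.mean(np.abs(t[ok] - e[ok]) / np.abs(t[ok])))


def protocol_sweep(
    model: CandidateModel,
    assumed_params: ParameterSet,
    consts: FixedConstants,
    design: ExperimentalDesign,
    periods_h: Sequence[float] = (1.0, 2.0, 4.0, 24.0, 48.0),
    noise_levels: Sequence[float] = NOISE_GRID,
    n_repeats: int = 5,
    fit_options: dict | None = None,
    seed: int = 0,
    error_mode: str = "elementwise",
    space: SearchSpace | None = None,
) -> pd.DataFrame:
    """Error table over (sampling period, noise level, repeat).

    ``fit_options`` carries the reduced multi-start budget used inside
    the sweep: keys ``n_starts`` (default 100) plus any stage options of
    :func:`cellgrowth.calibration.multistart_fit`.
    """
    fit_options = dict(fit_options or {})
    n_starts = int(fit_options.pop("n_starts", 100))
    names = model.free_parameter_names()
    theta_true = assumed_params.to_array(names)
    root = np.random.default_rng(seed)
    rows = []
    for period in periods_h:
        pdesign = replace(design, sampling_period_h=float(period))
        cond_map = dict(pdesign.conditions())
        for eps in noise_levels:
            for rep in range(n_repeats):
                sub_seed = int(root.integers(2**31 - 1))
                try:
                    data = generate_dataset(
                        model, assumed_params, consts, pdesign,
                        NoiseSpec(epsilon=float(eps), seed=sub_seed),
                    )
                    fit = multistart_fit(
                        model, consts, data, cond_map,
                        space=space, n_starts=n_starts, seed=sub_seed,
                        stage_options=fit_options,
                    )
                except Exception as err:
                    rows.append(
                        {"period_h": float(period), "epsilon": float(eps),
                         "repeat": rep, "error": np.nan, "failed": str(err)}
                    )
                    continue
                est = fit.theta_array()
                row = {
                    "period_h": float(period),
                    "epsilon": float(eps),
                    "repeat": rep,
                    "error": parameter_error(theta_true, est, error_mode),
                    "failed": "",
                }
                for nm, tv, ev in zip(names, theta_true, est):
                    row[f"err_{nm}"] = abs(tv - ev) / abs(tv) if tv else np.nan
                rows.append(row)
    return pd.DataFrame(rows)


def aggregate_errors(table: pd.DataFrame, by: str = "period_h") -> pd.DataFrame:
    """Mean/SD of the recovery error per period (averaged over the noise
    grid and repeats) or per (period, epsilon) with ``by='both'``."""
    keys = ["period_h", "epsilon"] if by == "both" else [by]
    ok = table[table["failed"] == ""]
    agg = ok.groupby(keys)["error"].agg(["mean", "std", "count"]).reset_index()
    return agg.rename(columns={"mean": "mean_error", "std": "sd_error"})


def recommend_period(
    table: pd.DataFrame, tolerance_ratio: float = 0.1
) -> float:
    """Coarsest sampling period whose mean error is within
    ``(1 + tolerance_ratio)`` of the best period's mean error."""
    if len(table) == 0:
        raise ValueError("empty protocol error table")
    agg = aggregate_errors(table)
    agg = agg.dropna(subset=["mean_error"])
    if len(agg) == 0:
        raise ValueError("no complete aggregates in the table")
    best = agg["mean_error"].min()
    ok = agg[agg["mean_error"] <= (1.0 + tolerance_ratio) * best]
    return float(ok["period_h"].max())
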
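"""Information-criterion model ranking, nested-limit reasoning and
goodness-of-fit / replicate-noise metrics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import FitResult, NLSObjective
from .models import (
    CandidateModel,
    CultureCondition,
    EffectKind,
    FixedConstants,
)
from .synthetic import TimeSeriesDataset


def information_criteria(k: int, loglik: float, ms: int) -> tuple[float, float]:
    """AIC = 2k - 2l ; BIC = k ln(ms) - 2l (natural logarithm)."""
    if ms < 1:
        raise ValueError("ms must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    aic = 2.0 * k - 2.0 * loglik
    bic = k * np.log(ms) - 2.0 * loglik
    return float(aic), float(bic)


@dataclass(frozen=True)
class SelectionRecord:
    model: CandidateModel
    k: int
    ms: int
    loglik: float
    aic: float
    bic: float
    n_first_order: int


def rank_models(
    fits: Mapping[str, FitResult] | Sequence[FitResult],
    selection_split: TimeSeriesDataset,
    consts: FixedConstants,
    conditions: Mapping[str, CultureCondition],
    weight_mode: str = "inverse_variance",
) -> list[SelectionRecord]:
    """Re-evaluate each calibrated model on the selection split and rank
    ascending by BIC (ties: fewer parameters, then model name).

    ``ms`` is the number of (condition, time, observable) summary cells in
    the selection split.  A model whose simulation fails on the selection
    split gets a non-finite BIC and ranks last.
    """
    if not isinstance(fits, Mapping):
        fits = {f.model.name: f for f in fits}
    ms = len(selection_split.summaries)
    records = []
    for name in sorted(fits):
        fit = fits[name]
        model = fit.model
        k = len(model.free_parameter_names())
        obj = NLSObjective(
            model, consts, selection_split, conditions, weight_mode
        )
        loss = obj(fit.theta_array())
        loglik = -loss
        if np.isfinite(loss) and loss < 1e11:
            aic, bic = information_criteria(k, loglik, ms)
        else:
            aic = bic = float("inf")
        records.append(
            SelectionRecord(model, k, ms, loglik, aic, bic, model.n_first_order)
        )
    records.sort(key=lambda r: (r.bic, r.k, r.model.name))
    return records


def selection_table(records: Sequence[SelectionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [r.model.name for r in records],
            "k": [r.k for r in records],
            "loglik": [r.loglik for r in records],
            "aic": [r.aic for r in records],
            "bic": [r.bic for r in records],
            "n_first_order": [r.n_first_order for r in records],
        }
    )


def nested_limit_check(
    model_a: CandidateModel, model_b: CandidateModel
) -> dict[str, str] | None:
    """Is ``model_b`` a limiting case of ``model_a``?

    An MMK-negative effect degenerates to zero-order as K -> infinity
    and an MMK-positive effect degenerates to zero-order as K -> 0.
    Returns the per-substrate limit map ({} for identical structures),
    or None when ``model_b`` is not reachable (limits can only remove
    MMK structure, never add it or change non-MMK kinds).
    """
    limits: dict[str, str] = {}
    for substrate, ka, kb in zip(
        ("oxygen", "glucose", "lactate"),
        model_a.kinds,
        model_b.kinds,
    ):
        if ka is kb:
            continue
        if ka is EffectKind.MMK_NEGATIVE and kb is EffectKind.ZERO_ORDER:
            limits[substrate] = "K -> inf"
        elif ka is EffectKind.MMK_POSITIVE and kb is EffectKind.ZERO_ORDER:
            limits[substrate] = "K -> 0"
        else:
            return None
    return limits


def _relative_terms(
    fit: FitResult,
    split: TimeSeriesDataset,
    consts: FixedConstants,
    conditions: Mapping[str, CultureCondition],
) -> np.ndarray:
    obj = NLSObjective(fit.model, consts, split, conditions, "unit")
    z = obj.predict(fit.theta_star)
    zbar = obj.zbar
    ok = zbar > 0
    if not np.all(ok):
        warnings.warn(
            f"{np.sum(~ok)} points with zero mean excluded from the error metric",
            stacklevel=3,
        )
    return np.abs(zbar[ok] - z[ok]) / zbar[ok]


def goodness_of_fit(
    fit: FitResult,
    validation_split: TimeSeriesDataset,
    consts: FixedConstants,
    conditions: Mapping[str, CultureCondition],
) -> float:
    """Mean relative prediction error |Zbar - z| / Zbar over all
    (condition, time, observable) cells of the split (a fraction)."""
    terms = _relative_terms(fit, validation_split, consts, conditions)
    if terms.size == 0:
        raise ValueError("no valid points in the validation split")
    return float(terms.mean())


def replicate_noise(dataset_split: TimeSeriesDataset) -> float:
    """Mean normalized replicate dispersion sigma / Zbar (a fraction)."""
    summ = dataset_split.summaries
    zbar = summ["mean"].to_numpy(float)
    sd = summ["sd"].to_numpy(float)
    ok = zbar > 0
    if not np.all(ok):
        warnings.warn(
            f"{np.sum(~ok)} points with zero mean excluded from the noise metric",
            stacklevel=2,
        )
    if not np.any(ok):
        raise ValueError("no valid points in the split")
    return float((sd[ok] / zbar[ok]).mean())
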
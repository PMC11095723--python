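"""Synthetic experiment generator.

Emulates the statistical structure of the in vitro study: a grid of
culture environments and seeding densities, a periodic measurement
schedule with a forced terminal sample, replicate-level multiplicative
Gaussian noise, and a stratified calibration/selection/validation split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models import (
    OBSERVABLES,
    CandidateModel,
    CultureCondition,
    FixedConstants,
    IntegrationError,
    ParameterSet,
    simulate_conditions,
)

#: noise levels used when sweeping measurement-error scenarios
NOISE_GRID = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)

SPLIT_LABELS = ("calibration", "selection", "validation")


@dataclass(frozen=True)
class ExperimentalDesign:
    """Factorial design: environments x seedings, with a shared schedule."""

    environments: tuple[tuple[float, float], ...]  # (glucose, oxygen) mol m^-3
    seedings: tuple[float, ...]  # cells/well
    replicates: int = 9
    sampling_period_h: float = 24.0
    first_sample_h: float = 6.0
    last_sample_h: float = 114.0
    cl0: float = 2.0  # initial lactate of fresh media (fixture default)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.sampling_period_h <= 0:
            raise ValueError("sampling_period_h must be positive")
        if self.first_sample_h > self.last_sample_h:
            raise ValueError("first_sample_h must not exceed last_sample_h")

    @property
    def n_conditions(self) -> int:
        return len(self.environments) * len(self.seedings)

    def conditions(self) -> list[tuple[str, CultureCondition]]:
        """(condition_id, condition) pairs in deterministic order."""
        out = []
        for ei, (cg0, co) in enumerate(self.environments):
            for si, n0 in enumerate(self.seedings):
                cid = f"env{ei}_seed{si}"
                out.append(
                    (cid, CultureCondition(n0=n0, cg0=cg0, cl0=self.cl0, co=co,
                                           horizon_h=self.last_sample_h))
                )
        return out

    def schedule(self) -> np.ndarray:
        return sampling_schedule(
            self.sampling_period_h, self.first_sample_h, self.last_sample_h
        )


def default_design(sampling_period_h: float = 24.0) -> ExperimentalDesign:
    """The study's design: {high 25, low 5.5} glucose x {0.18, 0.05} oxygen
    environments crossed with four seedings, nine replicates each."""
    return ExperimentalDesign(
        environments=((25.0, 0.18), (5.5, 0.18), (25.0, 0.05), (5.5, 0.05)),
        seedings=(25_000.0, 50_000.0, 100_000.0, 200_000.0),
        replicates=9,
        sampling_period_h=sampling_period_h,
    )


def sampling_schedule(
    period_h: float, first_h: float = 6.0, last_h: float = 114.0
) -> np.ndarray:
    """Sample times ``first_h + k*period_h`` up to ``last_h``, with the
    terminal time always appended (deduplicated, strictly increasing)."""
    if period_h <= 0:
        raise ValueError("period_h must be positive")
    if first_h > last_h:
        raise ValueError("first_h must not exceed last_h")
    n = int(np.floor((last_h - first_h) / period_h + 1e-9))
    times = first_h + period_h * np.arange(n + 1)
    if last_h - times[-1] > 1e-9 * max(1.0, period_h):
        times = np.append(times, last_h)
    else:
        times[-1] = last_h
    return times


@dataclass(frozen=True)
class NoiseSpec:
    """Relative multiplicative Gaussian measurement noise."""

    epsilon: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


def observe_with_noise(
    values: np.ndarray, noise: NoiseSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, int]:
    """Corrupt noiseless values: ``Z = z * (1 + eps * eta)``, eta ~ N(0,1).

    Negative draws are floored at 0 (states are physical); returns the
    corrupted array and the floored-draw count.
    """
    values = np.asarray(values, dtype=float)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    if noise.epsilon == 0.0:
        return values.copy(), 0
    eta = rng.standard_normal(values.shape)
    z = values * (1.0 + noise.epsilon * eta)
    n_floored = int(np.sum(z < 0))
    return np.maximum(z, 0.0), n_floored


@dataclass
class TimeSeriesDataset:
    """Replicate observations plus per-cell summaries.

    ``records`` columns: condition_id, replicate, time_h, observable,
    value, and (after :func:`split_dataset`) split.  ``summaries``
    columns: condition_id, time_h, observable, mean, sd.
    """

    records: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"condition_id", "replicate", "time_h", "observable", "value"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")

    @property
    def summaries(self) -> pd.DataFrame:
        def _sd(s: pd.Series) -> float:
            v = s.to_numpy(float)
            # identical replicates must give exactly 0 (noiseless contract)
            if len(v) < 2 or np.all(v == v[0]):
                return 0.0
            return float(np.std(v, ddof=1))

        grp = self.records.groupby(
            ["condition_id", "time_h", "observable"], sort=True
        )["value"]
        out = grp.agg(mean="mean", sd=_sd)
        return out.reset_index()

    @property
    def condition_ids(self) -> list[str]:
        return sorted(self.records["condition_id"].unique())

    def subset(self, split: str) -> "TimeSeriesDataset":
        if "split" not in self.records.columns:
            raise ValueError("dataset has no split labels; call split_dataset first")
        if split not in SPLIT_LABELS:
            raise ValueError(f"unknown split {split!r}")
        return TimeSeriesDataset(
            self.records[self.records["split"] == split].reset_index(drop=True),
            meta=dict(self.meta),
        )

    def __len__(self) -> int:
        return len(self.records)


def generate_dataset(
    model: CandidateModel,
    params: ParameterSet,
    consts: FixedConstants,
    design: ExperimentalDesign,
    noise: NoiseSpec,
    seed: int | None = None,
    solver_options: dict | None = None,
) -> TimeSeriesDataset:
    """Simulate every design condition, sample the schedule and draw
    ``design.replicates`` independent noisy copies per condition.

    Fully reproducible from ``seed`` (defaults to ``noise.seed``).
    """
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    times = design.schedule()
    pairs = design.conditions()
    conds = [c for _, c in pairs]
    try:
        sims = simulate_conditions(model, params, consts, conds, times, solver_options)
    except IntegrationError as err:
        raise IntegrationError(
            f"synthetic generation failed across the design: {err}", err.t_fail_h
        ) from err

    rows = []
    n_floored = 0
    for ci, (cid, _) in enumerate(pairs):
        for rep in range(design.replicates):
            noisy, nf = observe_with_noise(sims[ci], noise, rng)
            n_floored += nf
            for oi, obs in enumerate(OBSERVABLES):
                for ti, t in enumerate(times):
                    rows.append((cid, rep, float(t), obs, noisy[oi, ti]))
    records = pd.DataFrame(
        rows, columns=["condition_id", "replicate", "time_h", "observable", "value"]
    )
    return TimeSeriesDataset(
        records,
        meta={
            "epsilon": noise.epsilon,
            "seed": int(noise.seed if seed is None else seed),
            "n_floored": n_floored,
            "model": model.name,
        },
    )


def split_dataset(
    dataset: TimeSeriesDataset,
    fractions: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> TimeSeriesDataset:
    """Stratified calibration/selection/validation split.

    Splitting operates on (condition, time, observable) cells so all
    replicates of a measurement stay together and replicate SDs remain
    computable within every split.  Within each condition the cells are
    partitioned as close to the requested fractions as integer counts
    allow (largest-remainder rounding), deterministically under ``seed``.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size != 3 or np.any(fractions < 0) or abs(fractions.sum() - 1) > 1e-9:
        raise ValueError("fractions must be three non-negatives summing to 1")
    rng = np.random.default_rng(seed)
    records = dataset.records.copy()
    records["split"] = ""
    cells = records[["condition_id", "time_h", "observable"]].drop_duplicates()
    for cid, group in cells.groupby("condition_id", sort=True):
        k = len(group)
        if k < 3:
            warnings.warn(
                f"condition {cid} has only {k} cells; split is degenerate",
                stacklevel=2,
            )
        # largest-remainder apportionment of k cells over the 3 splits
        ideal = fractions * k
        counts = np.floor(ideal).astype(int)
        rem = ideal - counts
        for i in np.argsort(-rem)[: k - counts.sum()]:
            counts[i] += 1
        labels = np.repeat(SPLIT_LABELS, counts)
        order = rng.permutation(k)
        idx = group.index.to_numpy()[order]
        for j, i in enumerate(idx):
            row = cells.loc[i]
            mask = (
                (records["condition_id"] == cid)
                & (records["time_h"] == row["time_h"])
                & (records["observable"] == row["observable"])
            )
            records.loc[mask, "split"] = labels[j]
    out = TimeSeriesDataset(records, meta=dict(dataset.meta))
    out.meta["split_seed"] = int(seed)
    out.meta["split_fractions"] = tuple(float(f) for f in fractions)
    return out
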
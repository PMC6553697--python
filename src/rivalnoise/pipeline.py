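"""Orchestration of the simulated experiments.

The experiments mirror the psychophysical design: 60 s trials, a grid of
26 stimulus conditions (5 modulation frequencies x 5 modulation contrasts
plus an unmodulated baseline), and a *double pass* structure in which every
external noise sequence is presented twice with fresh internal noise, so
that the agreement between the two passes indexes how strongly the external
modulation (rather than internal noise) drives the percept.

All randomness derives from a single master seed through documented
spawn-key paths (see :mod:`rivalnoise.seeds`): identical plans with the
same master seed reproduce summary tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .metrics import (
    ConditionSummary,
    CorrelationFunction,
    Epoch,
    EpochList,
    PerceptTimecourse,
    autocorrelation,
    consistency,
    crosscorrelation,
    duration_stats,
    extract_epochs,
)
from .model import (
    ModelParams,
    Variant,
    integrate_trial,
    integrate_trial_fixed,
    no_oscillator_percept,
    percept_from_responses,
)
from .noise import (
    BandpassSpec,
    NoiseStream,
    PowerlawSpec,
    StimulusCondition,
    StimulusMode,
    make_condition_streams,
    make_powerlaw_noise,
)
from .seeds import child_seed
from .synthetic import load_human_summary

__all__ = [
    "ExperimentPlan",
    "HumanSummary",
    "run_double_pass",
    "sweep_internal_noise",
    "run_full_grid",
    "run_no_oscillator",
    "compare_to_human",
    "FREQUENCIES",
    "MODULATION_SDS",
    "INTERNAL_ALPHAS",
    "INTERNAL_SDS",
]

#: stimulus grid of the main experiment
FREQUENCIES: Tuple[float, ...] = (1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0)
MODULATION_SDS: Tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)

#: internal-noise grid of the amplitude x spectral-slope sweep
INTERNAL_ALPHAS: Tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
INTERNAL_SDS: Tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)


@dataclass(frozen=True)
class ExperimentPlan:
    """Everything needed to reproduce a simulation campaign.

    ``n_reps`` defaults to 200: stochastic summary values stabilise well
    before that (standard errors shrink as 1/sqrt(n)), and the original
    1000-repetition scale remains available by configuration.
    """

    frequencies: Tuple[float, ...] = FREQUENCIES
    modulation_sds: Tuple[float, ...] = MODULATION_SDS
    internal_alphas: Tuple[float, ...] = INTERNAL_ALPHAS
    internal_sds: Tuple[float, ...] = INTERNAL_SDS
    n_reps: int = 200
    duration: float = 60.0
    master_seed: int = 0
    variant: Variant = Variant.MAIN
    engine: str = "fast"  # "fast" (RK4 kernel) or "adaptive" (solve_ivp reference)
    transient: float = 2.0  # onset window discarded before all metrics (s)

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be at least 2")
        if not self.frequencies or not self.modulation_sds:
            raise ValueError("condition grids must be non-empty")
        if self.engine not in ("fast", "adaptive"):
            raise ValueError("engine must be 'fast' or 'adaptive'")


@dataclass(frozen=True)
class HumanSummary:
    """Published human group-level values available for model comparison.

    Cells are keyed by ``(centre_freq, modulation_sd)``; missing cells are
    simply absent.  Provenance tags distinguish printed values from
    approximate figure readings.
    """

    baseline_mean_duration: float
    baseline_consistency: float
    cells: Dict[Tuple[float, float], Dict[str, float]]
    provenance: dict = field(default_factory=dict)

    @classmethod
    def load(cls) -> "HumanSummary":
        raw = load_human_summary()
        cells: Dict[Tuple[float, float], Dict[str, float]] = {}
        for payload in raw.get("conditions", {}).values():
            key = (float(payload["centre_freq_hz"]), float(payload["modulation_sd_pct"]))
            cells[key] = {
                name: entry["value"]
                for name, entry in payload.items()
                if isinstance(entry, dict) and "value" in entry
            }
        return cls(
            baseline_mean_duration=raw["baseline"]["mean_duration_s"]["value"],
            baseline_consistency=raw["baseline"]["consistency"]["value"],
            cells=cells,
            provenance=raw,
        )


def _integrate(
    params: ModelParams,
    ext_l: NoiseStream,
    ext_r: NoiseStream,
    int_l: NoiseStream,
    int_r: NoiseStream,
    duration: float,
    engine: str,
):
    if engine == "adaptive":
        return integrate_trial(params, ext_l, ext_r, int_l, int_r, duration)
    return integrate_trial_fixed(params, ext_l, ext_r, int_l, int_r, duration)


def _internal_pair(
    params: ModelParams, duration: float, dt: float, seed: int, rep: int, pass_idx: int
) -> Tuple[NoiseStream, NoiseStream]:
    spec = lambda s: PowerlawSpec(params.internal_alpha, params.internal_sd, duration, dt, s)
    left = make_powerlaw_noise(spec(child_seed(seed, rep, 1, pass_idx, 0)))
    right = make_powerlaw_noise(spec(child_seed(seed, rep, 1, pass_idx, 1)))
    return left, right


def _pooled_hist(durations: np.ndarray):
    epochs = EpochList(tuple(Epoch(0, 0.0, float(d)) for d in durations))
    return duration_stats(epochs)


def run_double_pass(
    condition: StimulusCondition,
    params: ModelParams,
    n_reps: int,
    seed: int,
    duration: float = 60.0,
    engine: str = "fast",
    transient: float = 2.0,
    compute_correlations: bool = False,
    max_lag: float = 5.0,
) -> ConditionSummary:
    """Repeated double-pass simulation of one stimulus condition.

    Each repetition draws one external stream pair, integrates the model
    twice with fresh internal noise (the double-pass structure), computes
    the pass-pair consistency, and pools dominance epochs across both
    passes.  Consistency is averaged per pair then across repetitions; the
    onset ``transient`` is discarded before every metric.
    """
    durations: List[float] = []
    cons: List[float] = []
    acfs: List[np.ndarray] = []
    ccfs: List[np.ndarray] = []
    lags: Optional[np.ndarray] = None
    n_failed = 0

    for rep in range(n_reps):
        ext_l, ext_r = make_condition_streams(
            condition, child_seed(seed, rep, 0), duration=duration
        )
        percepts = []
        try:
            for pass_idx in range(2):
                if params.variant is Variant.NO_OSCILLATOR:
                    int_l, int_r = _internal_pair(
                        params, duration, ext_l.dt, seed, rep, pass_idx
                    )
                    p = no_oscillator_percept(ext_l, ext_r, int_l, int_r, duration)
                else:
                    int_l, int_r = _internal_pair(
                        params, duration, ext_l.dt, seed, rep, pass_idx
                    )
                    trial = _integrate(params, ext_l, ext_r, int_l, int_r, duration, engine)
                    p = percept_from_responses(trial)
                percepts.append(p.crop(transient))
        except (RuntimeError, FloatingPointError):
            n_failed += 1
            continue

        c = consistency(percepts[0], percepts[1])
        if c is not None:
            cons.append(c)
        for p in percepts:
            durations.extend(extract_epochs(p).complete_durations)
        if compute_correlations:
            diff = NoiseStream(ext_l.samples - ext_r.samples, ext_l.dt)
            # shift the noise grid to account for the cropped onset
            diff_cropped = NoiseStream(
                diff.samples[int(round(transient / diff.dt)) :], diff.dt
            )
            for p in percepts:
                acf = autocorrelation(p, max_lag)
                ccf = crosscorrelation(p, diff_cropped, max_lag)
                lags = acf.lags
                acfs.append(acf.coefficients)
                ccfs.append(ccf.coefficients)

    durations_arr = np.asarray(durations)
    mean_dur, edges, counts = _pooled_hist(durations_arr)
    summary = ConditionSummary(
        condition=condition.label,
        mean_duration=mean_dur,
        hist_edges=edges,
        hist_counts=counts,
        mean_consistency=float(np.mean(cons)) if cons else None,
        n_trials=2 * (n_reps - n_failed),
        n_epochs=int(durations_arr.size),
        sem_duration=(
            float(durations_arr.std(ddof=1) / np.sqrt(durations_arr.size))
            if durations_arr.size > 1
            else None
        ),
        sem_consistency=(
            float(np.std(cons, ddof=1) / np.sqrt(len(cons))) if len(cons) > 1 else None
        ),
        extras={"n_failed": n_failed, "variant": params.variant.value, "seed": seed},
    )
    if compute_correlations and acfs:
        summary.autocorr = CorrelationFunction(lags, np.nanmean(acfs, axis=0))
        summary.crosscorr = CorrelationFunction(lags, np.nanmean(ccfs, axis=0))
    return summary


def _sweep_condition(plan: ExperimentPlan) -> StimulusCondition:
    return StimulusCondition(
        StimulusMode.INDEPENDENT,
        BandpassSpec(1 / 8, 16.0, plan.duration),
    )


def sweep_internal_noise(
    plan: ExperimentPlan,
    condition: Optional[StimulusCondition] = None,
    base_params: Optional[ModelParams] = None,
) -> pd.DataFrame:
    """Internal-noise amplitude x spectral-slope sweep at one stimulus condition.

    The fixed condition defaults to (1/8 Hz, 16% contrast) -- the cell where
    external modulation engages the rivalry oscillation most strongly, hence
    the most diagnostic of internal-noise properties.
    """
    condition = condition if condition is not None else _sweep_condition(plan)
    base_params = base_params if base_params is not None else ModelParams(variant=plan.variant)
    rows = []
    for i, alpha in enumerate(plan.internal_alphas):
        for j, sd in enumerate(plan.internal_sds):
            params = replace(base_params, internal_alpha=alpha, internal_sd=sd)
            summary = run_double_pass(
                condition,
                params,
                plan.n_reps,
                child_seed(plan.master_seed, 1, i, j),
                duration=plan.duration,
                engine=plan.engine,
                transient=plan.transient,
            )
            rows.append(
                {
                    "alpha": alpha,
                    "internal_sd": sd,
                    "mean_duration": summary.mean_duration,
                    "mean_consistency": summary.mean_consistency,
                    "sem_duration": summary.sem_duration,
                    "sem_consistency": summary.sem_consistency,
                    "n_epochs": summary.n_epochs,
                    "n_trials": summary.n_trials,
                }
            )
    return pd.DataFrame(rows)


def grid_conditions(plan: ExperimentPlan) -> List[StimulusCondition]:
    """The 26 stimulus conditions: baseline plus frequency x contrast grid."""
    conditions = [StimulusCondition(StimulusMode.BASELINE)]
    for freq in plan.frequencies:
        for sd in plan.modulation_sds:
            conditions.append(
                StimulusCondition(
                    StimulusMode.INDEPENDENT, BandpassSpec(freq, sd, plan.duration)
                )
            )
    return conditions


def run_full_grid(
    plan: ExperimentPlan, params: Optional[ModelParams] = None
) -> Tuple[pd.DataFrame, Dict[str, ConditionSummary]]:
    """Simulate all 26 conditions with one model configuration.

    Returns a tidy table (one row per condition) and the full per-condition
    summaries keyed by condition label.
    """
    params = params if params is not None else ModelParams(variant=plan.variant)
    rows = []
    summaries: Dict[str, ConditionSummary] = {}
    for idx, condition in enumerate(grid_conditions(plan)):
        summary = run_double_pass(
            condition,
            params,
            plan.n_reps,
            child_seed(plan.master_seed, 2, idx),
            duration=plan.duration,
            engine=plan.engine,
            transient=plan.transient,
        )
        summaries[condition.label] = summary
        bp = condition.bandpass
        rows.append(
            {
                "condition": condition.label,
                "centre_freq": bp.centre_freq if bp else 0.0,
                "modulation_sd": bp.sd if bp else 0.0,
                "mean_duration": summary.mean_duration,
                "mean_consistency": summary.mean_consistency,
                "sem_duration": summary.sem_duration,
                "sem_consistency": summary.sem_consistency,
                "n_epochs": summary.n_epochs,
            }
        )
    return pd.DataFrame(rows), summaries


def run_no_oscillator(
    plan: ExperimentPlan,
    conditions: Optional[Sequence[StimulusCondition]] = None,
    params: Optional[ModelParams] = None,
) -> pd.DataFrame:
    """Comparator-only percepts (oscillatory mechanism removed) on a condition subset.

    Defaults to the 1/8 Hz column of the grid, the comparison shown against
    the full model.
    """
    params = (
        params
        if params is not None
        else ModelParams(variant=Variant.NO_OSCILLATOR)
    )
    if params.variant is not Variant.NO_OSCILLATOR:
        raise ValueError("run_no_oscillator requires the NO_OSCILLATOR variant")
    if conditions is None:
        conditions = [
            StimulusCondition(
                StimulusMode.INDEPENDENT, BandpassSpec(1 / 8, sd, plan.duration)
            )
            for sd in plan.modulation_sds
        ]
    rows = []
    for idx, condition in enumerate(conditions):
        summary = run_double_pass(
            condition,
            params,
            plan.n_reps,
            child_seed(plan.master_seed, 3, idx),
            duration=plan.duration,
            engine=plan.engine,
            transient=plan.transient,
        )
        bp = condition.bandpass
        rows.append(
            {
                "condition": condition.label,
                "centre_freq": bp.centre_freq if bp else 0.0,
                "modulation_sd": bp.sd if bp else 0.0,
                "mean_duration": summary.mean_duration,
                "mean_consistency": summary.mean_consistency,
            }
        )
    return pd.DataFrame(rows)


def compare_to_human(
    model_table: pd.DataFrame,
    human: HumanSummary,
    condition: Tuple[float, float] = (1 / 8, 16.0),
    weights: Tuple[float, float] = (1.0, 1.0),
) -> pd.DataFrame:
    """Rank internal-noise configurations by distance to the human summary.

    ``model_table`` is a sweep table (one row per (alpha, internal_sd) cell
    at a fixed stimulus condition).  The distance for each row is a weighted
    sum of squared relative discrepancies on mean dominance duration and on
    consistency against the human cell values; the full ranking is returned,
    not just the best row.
    """
    if condition not in human.cells:
        raise ValueError(f"no human data for condition {condition}")
    cell = human.cells[condition]
    h_dur = cell.get("mean_duration_s")
    h_cons = cell.get("consistency")
    if h_dur is None and h_cons is None:
        raise ValueError("human cell carries neither duration nor consistency")
    w_dur, w_cons = weights
    out = model_table.copy()
    dist = np.zeros(len(out))
    if h_dur is not None and w_dur > 0:
        dist = dist + w_dur * ((out["mean_duration"] - h_dur) / h_dur) ** 2
    if h_cons is not None and w_cons > 0:
        dist = dist + w_cons * ((out["mean_consistency"] - h_cons) / h_cons) ** 2
    out["distance"] = dist
    out = out.sort_values("distance").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
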
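"""Least-squares calibration of uptake parameters against batch profiles.

The original parameters were adjusted by trial and error against measured
concentration profiles; here that protocol is replaced by staged, bounded
derivative-free minimization of a weighted sum of squared residuals, with
optional seeded multistart for reproducibility.  Stages run in declared
order and later stages inherit earlier results as fixed values — e.g.
glucose parameters from an anaerobic batch first, then oxygen parameters
from an aerobic batch with the glucose parameters frozen.

Residuals are weighted per series by the inverse squared data maximum by
default, so g/L-scale sugars do not drown the mM-scale dissolved oxygen.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize

from .dfba_engine import BatchConditions, CultureState, SimulationResult, simulate_batch
from .metabolic_network import SpeciesModel

#: canonical series names -> trajectory columns
SERIES_COLUMNS = {
    "glucose": "glucose_g_L",
    "xylose": "xylose_g_L",
    "ethanol": "ethanol_g_L",
    "biomass_cerevisiae": "X_cerevisiae_gdw_L",
    "biomass_stipitis": "X_stipitis_gdw_L",
    "biomass_total": None,  # sum of the two biomass columns
    "oxygen": "DO_mM",
}


@dataclass
class BatchDataset:
    """Measured (or synthetic) concentration series from one batch.

    ``series`` maps canonical names (keys of :data:`SERIES_COLUMNS`) to
    arrays aligned with ``time``; missing points are NaN.  ``metadata``
    carries at least the operating conditions needed to re-simulate the
    batch (``kla``, ``initial``, ``context``) and, for synthetic data, the
    generating parameters under ``ground_truth``.
    """

    time: np.ndarray
    series: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.metadata.get("kla", 0.0) < 0:
            raise ValueError("metadata kLa must be nonnegative")
        for name, values in list(self.series.items()):
            values = np.asarray(values, dtype=float)
            if values.shape != self.time.shape:
                raise ValueError(
                    f"series {name!r} has {values.shape}, time has {self.time.shape}"
                )
            if name not in SERIES_COLUMNS:
                raise ValueError(f"unknown series {name!r}")
            self.series[name] = values

    def conditions(self, t_end: float | None = None, **overrides) -> BatchConditions:
        """Reconstruct the batch operating conditions from the metadata."""
        meta = self.metadata
        init = dict(meta["initial"])
        init.pop("t", None)
        kw = {
            "kla": meta["kla"],
            "o_star": meta.get("o_star", 0.24),
            "context": meta.get("context", "co_culture"),
            "initial": CultureState(**init),
            "t_end": t_end or meta.get("t_end") or float(self.time[-1]) + 0.5,
        }
        kw.update(overrides)
        return BatchConditions(**kw)

    def to_csv(self, path_or_buf) -> None:
        """Wide-form CSV: metadata as ``# key=json`` comments, then a table
        with ``time_h`` plus one column per series."""
        frame = pd.DataFrame({"time_h": self.time})
        for name, values in self.series.items():
            frame[name] = values
        header = "".join(
            f"# {key}={json.dumps(value)}\n" for key, value in self.metadata.items()
        )
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(header)
            frame.to_csv(path_or_buf, index=False)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(header)
                frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "BatchDataset":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        metadata = {}
        for line in text.splitlines():
            if not line.startswith("#"):
                break
            key, _, raw = line.lstrip("# ").partition("=")
            metadata[key.strip()] = json.loads(raw)
        frame = pd.read_csv(io.StringIO(text), comment="#")
        time = frame.pop("time_h").to_numpy()
        series = {name: frame[name].to_numpy() for name in frame.columns}
        return cls(time=time, series=series, metadata=metadata)


def _simulated_series(sim: SimulationResult, name: str) -> np.ndarray:
    traj = sim.trajectory
    if name == "biomass_total":
        return (
            traj["X_cerevisiae_gdw_L"] + traj["X_stipitis_gdw_L"]
        ).to_numpy()
    return traj[SERIES_COLUMNS[name]].to_numpy()


def default_weights(data: BatchDataset) -> dict[str, float]:
    """Inverse squared data maximum per series (1.0 for all-zero series)."""
    weights = {}
    for name, values in data.series.items():
        peak = np.nanmax(np.abs(values)) if np.any(np.isfinite(values)) else 0.0
        weights[name] = 1.0 / peak**2 if peak > 0 else 1.0
    return weights


def profile_sse(
    sim: SimulationResult,
    data: BatchDataset,
    weights: dict[str, float] | None = None,
) -> float:
    """Weighted sum of squared residuals between simulation and data.

    Simulated values are interpolated to the sample times with a monotone
    piecewise-cubic (PCHIP) scheme; NaN data points are skipped.  Raises
    when the dataset shares no series with the simulation output or the
    simulation does not cover the data time span.
    """
    t_sim = sim.trajectory["time_h"].to_numpy()
    if data.time[-1] > t_sim[-1] + 1e-6:
        raise ValueError(
            f"simulation ends at {t_sim[-1]} h but data extend to {data.time[-1]} h"
        )
    if weights is None:
        weights = default_weights(data)
    sse, matched = 0.0, 0
    for name, observed in data.series.items():
        if name not in SERIES_COLUMNS:
            continue
        matched += 1
        predicted = PchipInterpolator(t_sim, _simulated_series(sim, name))(
            np.clip(data.time, t_sim[0], t_sim[-1])
        )
        mask = np.isfinite(observed)
        resid = predicted[mask] - observed[mask]
        sse += weights.get(name, 1.0) * float(resid @ resid)
    if matched == 0:
        raise ValueError("dataset shares no series with the simulation output")
    return sse


@dataclass(frozen=True)
class FitStage:
    """One stage of the staged estimation protocol.

    ``free`` maps ``"<species>.<param>"`` names to (lower, upper) bounds;
    ``fixed`` pins named parameters to values for this and later stages;
    ``datasets`` are indices into the dataset list.
    """

    free: dict[str, tuple[float, float]]
    datasets: tuple[int, ...]
    fixed: dict[str, float] = field(default_factory=dict)
    weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        for name, (lo, hi) in self.free.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                raise ValueError(f"bounds for {name} must be finite, positive, lo<hi")


@dataclass(frozen=True)
class FitSpec:
    stages: tuple[FitStage, ...]
    maxfev: int = 200
    xatol: float = 1e-3
    fatol: float = 1e-8
    n_starts: int = 1
    seed: int = 0


def _apply_params(models: dict[str, SpeciesModel], values: dict[str, float]):
    updated = dict(models)
    by_species: dict[str, dict[str, float]] = {}
    for name, value in values.items():
        species, _, param = name.partition(".")
        if species not in updated:
            raise KeyError(f"unknown species in parameter {name!r}")
        by_species.setdefault(species, {})[param] = value
    for species, params in by_species.items():
        model = updated[species]
        updated[species] = model.with_uptake(model.uptake.with_(**params))
    return updated


def fit_uptake_parameters(
    spec: FitSpec,
    models: dict[str, SpeciesModel],
    datasets: list[BatchDataset],
    *,
    sim_options: dict | None = None,
    check_identifiability: bool = False,
) -> tuple[dict[str, SpeciesModel], dict]:
    """Staged bounded least-squares estimation of uptake parameters.

    Returns the updated species models and a report with, per stage, the
    SSE trace, the best parameters, and the optimizer status.  With
    ``n_starts > 1`` the extra starts are drawn uniformly inside the
    bounds from a generator seeded by ``spec.seed`` (deterministic).
    Non-convergence is flagged in the report; the best-so-far values are
    still returned.
    """
    sim_options = dict(sim_options or {})
    sim_options.setdefault("rtol", 1e-4)
    sim_options.setdefault("atol", 1e-7)
    current = dict(models)
    report: dict = {"stages": []}
    rng = np.random.default_rng(spec.seed)

    for stage_no, stage in enumerate(spec.stages):
        current = _apply_params(current, stage.fixed)
        names = sorted(stage.free)
        lo = np.array([stage.free[n][0] for n in names])
        hi = np.array([stage.free[n][1] for n in names])
        stage_data = [datasets[i] for i in stage.datasets]
        conds = [d.conditions() for d in stage_data]
        order = sorted(current)
        trace: list[float] = []

        def objective(x: np.ndarray) -> float:
            values = dict(zip(names, np.clip(x, lo, hi)))
            trial = _apply_params(current, values)
            model_list = [trial[k] for k in order]
            total = 0.0
            for data, cond in zip(stage_data, conds):
                sim = simulate_batch(model_list, cond, **sim_options)
                total += profile_sse(sim, data, stage.weights)
            trace.append(total)
            return total

        x0 = np.sqrt(lo * hi)  # geometric midpoint of the box
        starts = [x0]
        for _ in range(spec.n_starts - 1):
            starts.append(lo + (hi - lo) * rng.random(len(names)))

        identifiability = {}
        if check_identifiability:
            f0 = objective(x0)
            for k, name in enumerate(names):
                bumped = x0.copy()
                bumped[k] = min(bumped[k] * 1.1, hi[k])
                identifiability[name] = abs(objective(bumped) - f0) > 1e-12 * (1 + f0)

        best = None
        for x_start in starts:
            res = minimize(
                objective, x_start, method="Nelder-Mead",
                bounds=np.column_stack([lo, hi]),
                options={
                    "maxfev": spec.maxfev, "xatol": spec.xatol,
                    "fatol": spec.fatol,
                },
            )
            if best is None or res.fun < best.fun:
                best = res
        values = dict(zip(names, np.clip(best.x, lo, hi)))
        current = _apply_params(current, values)
        report["stages"].append(
            {
                "stage": stage_no,
                "parameters": values,
                "fixed": dict(stage.fixed),
                "sse": float(best.fun),
                "n_evaluations": len(trace),
                "sse_trace": trace,
                "converged": bool(best.success),
                "identifiable": identifiability,
            }
        )
    report["final_params"] = {
        label: model.uptake.to_dict() for label, model in current.items()
    }
    return current, report
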
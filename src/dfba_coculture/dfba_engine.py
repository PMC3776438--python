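"""Batch co-culture simulation: extracellular balances around the community LP.

State variables are the two biomass densities X_c and X_s (gdw/L), glucose
G, xylose Z and ethanol E (g/L) and dissolved oxygen O (mM).  At every
right-hand-side evaluation the kinetic uptake caps are computed from the
current concentrations, the community LP is solved, and the per-species
growth rates and exchange fluxes drive

    dXc/dt = mu_c Xc              dXs/dt = mu_s Xs
    dG/dt  = (v_gc Xc + v_gs Xs) M_glc        (uptake fluxes are negative)
    dZ/dt  = v_zs Xs M_xyl
    dE/dt  = (v_ec Xc + v_es Xs) M_eth
    dO/dt  = v_oc Xc + v_os Xs + kLa (O* - O)

with molar masses M converting mmol/L/h to g/L/h.  Oxygen enters through a
film model: the sparge rate maps linearly to the transfer coefficient kLa,
and O* is the saturation concentration (0.24 mM for water at 30 C, 1 atm).

The glucose-fermenting member cannot meet its non-growth ATP maintenance
demand once glucose is exhausted, which would make the whole community LP
infeasible; following the original protocol, its maintenance lower bound
is dropped to zero after glucose depletion (the "maintenance toggle").
The ODE system is stiff — oxygen equilibrates orders of magnitude faster
than the sugars — and is integrated with an implicit adaptive method,
restarting at the located glucose-depletion event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .metabolic_network import CommunityLP, FluxSolution, SpeciesModel
from .synthetic_data import community_of
from .uptake_kinetics import uptake_caps

#: g/mmol; fixed conversion constants for the three carbon species
MOLAR_MASSES = {"glucose": 0.18016, "xylose": 0.15013, "ethanol": 0.04607}

#: sparge-rate (cc/min) -> kLa (1/h) calibration points
_SPARGE_POINTS = ((25.0, 5.5), (50.0, 10.1))

#: kLa above which the model leaves its validated envelope (ethanol
#: reassimilation is not captured)
KLA_VALIDATED_MAX = 10.1

GLUCOSE_DEPLETION_THRESHOLD = 1e-6  # g/L


class IntegrationError(RuntimeError):
    """Integrator failure, with the last state and LP status attached."""

    def __init__(self, message, last_state=None, last_status=None):
        super().__init__(message)
        self.last_state = last_state
        self.last_status = last_status


@dataclass(frozen=True)
class CultureState:
    """Extracellular state at one time point."""

    t: float = 0.0
    X_c: float = 0.0
    X_s: float = 0.0
    G: float = 0.0
    Z: float = 0.0
    E: float = 0.0
    O: float = 0.24

    def __post_init__(self) -> None:
        for name in ("X_c", "X_s", "G", "Z", "E", "O"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} in culture state")

    def to_vector(self) -> np.ndarray:
        return np.array([self.X_c, self.X_s, self.G, self.Z, self.E, self.O])

    def to_dict(self) -> dict:
        return {
            "t": self.t, "X_c": self.X_c, "X_s": self.X_s,
            "G": self.G, "Z": self.Z, "E": self.E, "O": self.O,
        }


@dataclass(frozen=True)
class BatchConditions:
    """Operating conditions of one batch fermentation."""

    kla: float
    initial: CultureState
    o_star: float = 0.24
    t_end: float = 40.0
    context: str = "co_culture"
    molar_masses: dict = field(default_factory=lambda: dict(MOLAR_MASSES))
    glucose_depletion_threshold: float = GLUCOSE_DEPLETION_THRESHOLD
    stop_at_xylose: float | None = None

    def __post_init__(self) -> None:
        if self.kla < 0:
            raise ValueError("kLa must be nonnegative")
        if not self.o_star > 0:
            raise ValueError("O* must be positive")
        if self.context not in ("pure_culture", "co_culture"):
            raise ValueError(f"unknown context {self.context!r}")


@dataclass
class SimulationResult:
    """Trajectory, per-step flux solutions, events and batch metrics."""

    trajectory: pd.DataFrame
    flux_trace: list[FluxSolution]
    events: dict
    metrics: dict
    conditions: BatchConditions

    def state_at(self, index: int) -> CultureState:
        row = self.trajectory.iloc[index]
        return CultureState(
            t=row["time_h"], X_c=max(row["X_cerevisiae_gdw_L"], 0.0),
            X_s=max(row["X_stipitis_gdw_L"], 0.0), G=max(row["glucose_g_L"], 0.0),
            Z=max(row["xylose_g_L"], 0.0), E=max(row["ethanol_g_L"], 0.0),
            O=max(row["DO_mM"], 0.0),
        )


def kla_from_sparge(q: float) -> float:
    """Linear sparge-rate (cc/min) to kLa (1/h) map through the two
    gassing-out calibration points (25 -> 5.5, 50 -> 10.1)."""
    if q < 0:
        raise ValueError("sparge rate must be nonnegative")
    (q1, k1), (q2, k2) = _SPARGE_POINTS
    slope = (k2 - k1) / (q2 - q1)
    return k1 + slope * (q - q1)


def _biomass_slots(models: list[SpeciesModel]) -> list[int]:
    """Map each member to a state-vector biomass slot (0 = X_c, 1 = X_s)."""
    if not 1 <= len(models) <= 2:
        raise ValueError("the engine supports one or two species")
    slots, taken = [], set()
    for m in models:
        label = m.label.lower()
        if "cerevisiae" in label and 0 not in taken:
            slot = 0
        elif "stipitis" in label and 1 not in taken:
            slot = 1
        else:
            slot = 0 if 0 not in taken else 1
        slots.append(slot)
        taken.add(slot)
    return slots


def _toggle_bounds(models: list[SpeciesModel]) -> dict:
    """Zero the maintenance lower bound of glucose-only members.

    These are the members (the respiratory-deficient S. cerevisiae in the
    study system) that cannot generate ATP once glucose is gone.
    """
    out = {}
    for m in models:
        if m.uptake.v_z_max is not None:
            continue
        net = m.effective_network()
        rid = net.maintenance_reaction_id
        if rid is None:
            continue
        j = net.index(rid)
        out[m.label] = {rid: (0.0, float(net.upper_bounds[j]))}
    return out


def maintenance_toggle(
    G: float, models: list[SpeciesModel],
    threshold: float = GLUCOSE_DEPLETION_THRESHOLD,
) -> dict:
    """Bound overrides implementing the post-glucose maintenance relief.

    Returns ``{label: {maintenance_rxn: (0, ub)}}`` when glucose is below
    the depletion threshold, an empty dict otherwise.
    """
    if G >= threshold:
        return {}
    return _toggle_bounds(models)


class _Engine:
    def __init__(self, models, cond, parsimonious=True):
        self.models = models
        self.cond = cond
        self.slots = _biomass_slots(models)
        self.community = community_of(models)
        self.lp = CommunityLP(self.community)
        self.parsimonious = parsimonious
        self.toggle = _toggle_bounds(models) if cond.context == "co_culture" else {}
        self.last_status = "unsolved"

    def solve(self, y, toggled: bool) -> FluxSolution:
        G, Z, E, O = (max(v, 0.0) for v in y[2:6])
        bounds = {
            m.label: uptake_caps(G, Z, E, O, m.uptake) for m in self.models
        }
        extra = self.toggle if (toggled and self.toggle) else None
        sol = self.lp.solve(bounds, extra, parsimonious=self.parsimonious)
        if not sol.optimal and not toggled and self.toggle:
            sol = self.lp.solve(bounds, self.toggle, parsimonious=self.parsimonious)
        self.last_status = sol.status
        return sol

    def rhs(self, t, y, toggled: bool) -> np.ndarray:
        cond = self.cond
        sol = self.solve(y, toggled)
        dy = np.zeros(6)
        G, Z, E, O = (max(v, 0.0) for v in y[2:6])
        if sol.optimal:
            mm = cond.molar_masses
            for m, slot in zip(self.models, self.slots):
                X = max(y[slot], 0.0)
                fx = sol.members[m.label]
                dy[slot] += fx.mu * X
                dy[2] += fx.exchange["glucose"] * X * mm["glucose"]
                dy[3] += fx.exchange["xylose"] * X * mm["xylose"]
                dy[4] += fx.exchange["ethanol"] * X * mm["ethanol"]
                dy[5] += fx.exchange["oxygen"] * X
        # if infeasible even after the toggle: growth and exchange are zero
        dy[5] += cond.kla * (cond.o_star - O)
        # freeze depleted pools against integrator overshoot
        for i in range(6):
            if y[i] <= 0.0 and dy[i] < 0.0:
                dy[i] = 0.0
        return dy


def rhs(
    state: CultureState,
    models: list[SpeciesModel],
    cond: BatchConditions,
    *,
    toggled: bool | None = None,
) -> tuple[CultureState, FluxSolution]:
    """Time derivatives of the extracellular state at one point.

    Returns ``(deriv, solution)`` where ``deriv`` maps each state field to
    its d/dt value and ``solution`` is the flux solution used.  ``toggled``
    defaults to glucose-below-threshold in co-culture context.
    """
    engine = _Engine(models, cond)
    if toggled is None:
        toggled = (
            cond.context == "co_culture"
            and state.G < cond.glucose_depletion_threshold
        )
    y = state.to_vector()
    sol = engine.solve(y, toggled)
    dy = engine.rhs(state.t, y, toggled)
    deriv = dict(zip(("X_c", "X_s", "G", "Z", "E", "O"), dy))
    return deriv, sol


def simulate_batch(
    models: list[SpeciesModel] | SpeciesModel,
    cond: BatchConditions,
    *,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    dt_out: float = 0.1,
    xylose_cutoff: float = 0.5,
    parsimonious: bool = True,
    method: str = "BDF",
) -> SimulationResult:
    """Integrate a batch fermentation and compute its performance metrics.

    The integration runs in two phases split at the located
    glucose-depletion event (co-culture context only): before it the
    maintenance demand is enforced, after it the fermentative member's
    maintenance bound is relaxed.  Output is reported on a uniform grid of
    spacing ``dt_out`` plus the event times.
    """
    if isinstance(models, SpeciesModel):
        models = [models]
    if cond.kla > KLA_VALIDATED_MAX + 1e-9:
        warnings.warn(
            f"kLa={cond.kla} exceeds the validated envelope "
            f"(<= {KLA_VALIDATED_MAX} 1/h); ethanol reassimilation is not "
            "modelled at high aeration",
            stacklevel=2,
        )
    engine = _Engine(models, cond, parsimonious=parsimonious)
    y0 = np.maximum(cond.initial.to_vector(), 0.0)
    t_grid = np.arange(0.0, cond.t_end + dt_out / 2, dt_out)
    t_grid[-1] = min(t_grid[-1], cond.t_end)

    segments = []

    def integrate(t0, tf, y_start, toggled):
        t_eval = t_grid[(t_grid > t0 + 1e-12) & (t_grid <= tf + 1e-12)]
        events = []
        if not toggled and cond.context == "co_culture":
            def glucose_event(t, y, *args):
                return y[2] - cond.glucose_depletion_threshold
            glucose_event.terminal = True
            glucose_event.direction = -1
            events.append(glucose_event)
        if cond.stop_at_xylose is not None:
            def xylose_event(t, y, *args):
                return y[3] - cond.stop_at_xylose
            xylose_event.terminal = True
            xylose_event.direction = -1
            events.append(xylose_event)
        sol = solve_ivp(
            engine.rhs, (t0, tf), y_start, method=method,
            t_eval=t_eval if len(t_eval) else None,
            events=events or None, args=(toggled,),
            rtol=rtol, atol=atol, max_step=max(cond.t_end / 10, 1.0),
        )
        if sol.status == -1:
            raise IntegrationError(
                f"integration failed at t={sol.t[-1] if len(sol.t) else t0}: "
                f"{sol.message}",
                last_state=sol.y[:, -1] if sol.y.size else y_start,
                last_status=engine.last_status,
            )
        return sol

    toggled = False
    t0, y = 0.0, y0
    rows = [(0.0, y0.copy(), toggled)]
    while True:
        sol = integrate(t0, cond.t_end, y, toggled)
        segments.append(sol)
        for tk, yk in zip(sol.t, sol.y.T):
            rows.append((tk, yk, toggled))
        if sol.status != 1:
            break
        # identify which terminal event fired (same order as registered)
        names = []
        if not toggled and cond.context == "co_culture":
            names.append("glucose")
        if cond.stop_at_xylose is not None:
            names.append("xylose")
        fired = None
        for i, name in enumerate(names):
            if len(sol.t_events[i]):
                cand = (float(sol.t_events[i][0]), name, np.asarray(sol.y_events[i][0]))
                if fired is None or cand[0] < fired[0]:
                    fired = cand
        if fired is None:
            break
        t_ev, name, y_ev = fired
        if name == "xylose":
            rows.append((t_ev, y_ev, toggled))
            break
        # glucose depletion: relax maintenance and restart (fires at most once)
        toggled = True
        rows.append((t_ev, y_ev, toggled))
        t0, y = t_ev, y_ev
        if t0 >= cond.t_end - 1e-9:
            break

    rows.sort(key=lambda r: r[0])
    times, states, flags = [], [], []
    for tk, yk, fl in rows:
        if times and tk <= times[-1] + 1e-12:
            continue
        times.append(float(tk))
        states.append(np.maximum(yk, 0.0))
        flags.append(fl)
    Y = np.array(states)

    traj = pd.DataFrame(
        {
            "time_h": times,
            "X_cerevisiae_gdw_L": Y[:, 0],
            "X_stipitis_gdw_L": Y[:, 1],
            "glucose_g_L": Y[:, 2],
            "xylose_g_L": Y[:, 3],
            "ethanol_g_L": Y[:, 4],
            "DO_mM": Y[:, 5],
        }
    )

    flux_trace = [engine.solve(Y[i], flags[i]) for i in range(len(times))]

    events = {
        "glucose_depletion_time_h": _crossing_time(
            traj["time_h"].to_numpy(), traj["glucose_g_L"].to_numpy(),
            cond.glucose_depletion_threshold,
        ),
        "xylose_depletion_time_h": _crossing_time(
            traj["time_h"].to_numpy(), traj["xylose_g_L"].to_numpy(),
            xylose_cutoff,
        ),
    }

    result = SimulationResult(
        trajectory=traj, flux_trace=flux_trace, events=events,
        metrics={}, conditions=cond,
    )
    result.metrics = batch_metrics(result, xylose_cutoff)
    return result


def _crossing_time(t: np.ndarray, y: np.ndarray, threshold: float) -> float | None:
    """First downward crossing of ``y`` below ``threshold``, interpolated."""
    if y[0] < threshold:
        return 0.0
    below = np.nonzero(y < threshold)[0]
    if len(below) == 0:
        return None
    k = below[0]
    t0, t1, y0, y1 = t[k - 1], t[k], y[k - 1], y[k]
    if y0 == y1:
        return float(t1)
    return float(t0 + (y0 - threshold) * (t1 - t0) / (y0 - y1))


def batch_metrics(result: SimulationResult, xylose_cutoff: float = 0.5) -> dict:
    """Titer, batch time and productivity of a simulated batch.

    Batch time is the first (interpolated) crossing of xylose below the
    cutoff; titer is the ethanol concentration at that time; productivity
    is titer over batch time.  When the cutoff is never crossed, or is
    crossed at t=0, the metrics are flagged undefined rather than raising,
    so grid optimization can penalize such designs.
    """
    traj = result.trajectory
    if not len(traj):
        raise ValueError("empty trajectory")
    t = traj["time_h"].to_numpy()
    z = traj["xylose_g_L"].to_numpy()
    e = traj["ethanol_g_L"].to_numpy()
    batch_time = _crossing_time(t, z, xylose_cutoff)
    base = {"xylose_cutoff_g_L": xylose_cutoff}
    if batch_time is None or batch_time <= 0.0:
        return {
            **base,
            "defined": False,
            "batch_time_h": 0.0 if batch_time == 0.0 else float("nan"),
            "ethanol_titer_g_L": float("nan"),
            "productivity_g_L_h": float("nan"),
        }
    titer = float(np.interp(batch_time, t, e))
    return {
        **base,
        "defined": True,
        "batch_time_h": float(batch_time),
        "ethanol_titer_g_L": titer,
        "productivity_g_L_h": titer / batch_time,
    }
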
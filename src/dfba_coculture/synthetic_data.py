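"""Hand-solvable toy networks and synthetic batch datasets.

The toy metabolism is a minimal Crabtree-style core: glucose can be
fermented (little ATP, ethanol secreted) or respired (much ATP, consumes
oxygen, mitochondrial), xylose catabolism needs some oxygen and yields
ethanol plus intermediate ATP, ethanol can optionally be respired, a fixed
non-growth ATP maintenance drain must be met, and growth is a pure ATP
sink.  Every FBA optimum of such a network is a short greedy allocation of
oxygen across the routes ranked by ATP per O2, so expected values for
tests can be computed by hand.

The default community pairs a respiratory-deficient glucose-only
"cerevisiae-like" member with a glucose+xylose "stipitis-like" member
carrying the published co-culture transport parameters, so the simulated
batches show the same qualitative phases as the measured ones: an initial
respiratory transient while dissolved oxygen is drawn down, fermentative
glucose consumption, diauxic switch-over, and an oxygen-transfer-limited
xylose phase.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .metabolic_network import (
    CommunityNetwork,
    ConfigurationError,
    FluxSolution,
    MemberFluxes,
    MetabolicNetwork,
    SpeciesModel,
    combine_networks,
)
from .uptake_kinetics import UptakeParams, table_params

_KNOWN_SUBSTRATES = ("glucose", "xylose", "ethanol")


@dataclass(frozen=True)
class ToyNetworkConfig:
    """Stoichiometric yields of the toy core metabolism.

    ATP yields are mmol ATP per mmol substrate; ``atp_per_biomass`` is the
    ATP cost of one gram (dry weight) of biomass, so a growth rate of
    mu 1/h drains ``atp_per_biomass * mu`` mmol ATP/gdw/h.  Integer-friendly
    defaults (2 fermentative vs 26 respiratory ATP per glucose) keep oracle
    arithmetic exact.
    """

    substrates: tuple[str, ...] = ("glucose",)
    atp_per_glucose_ferm: float = 2.0
    ethanol_per_glucose: float = 2.0
    atp_per_glucose_resp: float = 26.0
    o2_per_glucose_resp: float = 6.0
    atp_per_xylose: float = 4.0
    o2_per_xylose: float = 0.5
    ethanol_per_xylose: float = 1.5
    atp_per_ethanol: float = 13.0
    o2_per_ethanol: float = 3.0
    atp_per_biomass: float = 100.0
    maintenance: float = 1.0
    flux_cap: float = 1000.0

    def __post_init__(self) -> None:
        for name in (
            "atp_per_glucose_ferm", "ethanol_per_glucose",
            "atp_per_glucose_resp", "o2_per_glucose_resp",
            "atp_per_xylose", "o2_per_xylose", "ethanol_per_xylose",
            "atp_per_ethanol", "o2_per_ethanol", "atp_per_biomass",
            "flux_cap",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.maintenance < 0:
            raise ConfigurationError("maintenance must be nonnegative")
        if not self.atp_per_glucose_ferm < self.atp_per_glucose_resp:
            raise ConfigurationError(
                "fermentative ATP yield must be below the respiratory yield"
            )
        unknown = set(self.substrates) - set(_KNOWN_SUBSTRATES)
        if unknown:
            raise ConfigurationError(f"unknown substrates {sorted(unknown)}")
        if not self.substrates:
            raise ConfigurationError("at least one substrate required")


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian measurement noise for synthetic datasets."""

    level: float = 0.05
    interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("noise level must be nonnegative")
        if not self.interval > 0:
            raise ValueError("sampling interval must be positive")


def make_toy_species(
    cfg: ToyNetworkConfig,
    label: str = "cerevisiae",
    params: UptakeParams | None = None,
    knockouts: tuple[str, ...] = (),
) -> SpeciesModel:
    """Build a small species model whose FBA optimum is hand-computable.

    The network has at most 11 reactions: one exchange per included
    substrate plus ethanol and oxygen exchanges, a fermentation and a
    (mitochondrial) respiration route for glucose, an oxygen-requiring
    xylose route, an optional mitochondrial ethanol-respiration route,
    the ATP maintenance drain and the biomass sink.
    """
    cap = cfg.flux_cap
    metabolites = ["atp_c", "etoh_e", "o2_e"]
    if "glucose" in cfg.substrates:
        metabolites.insert(0, "glc_e")
    if "xylose" in cfg.substrates:
        metabolites.insert(-2, "xyl_e")

    columns: dict[str, dict[str, float]] = {}
    bounds: dict[str, tuple[float, float]] = {}
    compartment: dict[str, str] = {}

    def add(rid, coeffs, lb, ub, comp="cytoplasm"):
        columns[rid] = coeffs
        bounds[rid] = (lb, ub)
        compartment[rid] = comp

    if "glucose" in cfg.substrates:
        add("EX_glc", {"glc_e": -1.0}, -cap, 0.0, "extracellular")
        add(
            "FERM",
            {
                "glc_e": -1.0,
                "atp_c": cfg.atp_per_glucose_ferm,
                "etoh_e": cfg.ethanol_per_glucose,
            },
            0.0, cap,
        )
        add(
            "RESP",
            {
                "glc_e": -1.0,
                "o2_e": -cfg.o2_per_glucose_resp,
                "atp_c": cfg.atp_per_glucose_resp,
            },
            0.0, cap, "mitochondria",
        )
    if "xylose" in cfg.substrates:
        add("EX_xyl", {"xyl_e": -1.0}, -cap, 0.0, "extracellular")
        add(
            "XCAT",
            {
                "xyl_e": -1.0,
                "o2_e": -cfg.o2_per_xylose,
                "atp_c": cfg.atp_per_xylose,
                "etoh_e": cfg.ethanol_per_xylose,
            },
            0.0, cap,
        )
    ethanol_lb = -cap if "ethanol" in cfg.substrates else 0.0
    add("EX_etoh", {"etoh_e": -1.0}, ethanol_lb, cap, "extracellular")
    if "ethanol" in cfg.substrates:
        add(
            "ETOH_RESP",
            {
                "etoh_e": -1.0,
                "o2_e": -cfg.o2_per_ethanol,
                "atp_c": cfg.atp_per_ethanol,
            },
            0.0, cap, "mitochondria",
        )
    add("EX_o2", {"o2_e": -1.0}, -cap, 0.0, "extracellular")
    add("ATPM", {"atp_c": -1.0}, cfg.maintenance, cap)
    add("BIOMASS", {"atp_c": -cfg.atp_per_biomass}, 0.0, cap)

    reaction_ids = list(columns)
    S = np.zeros((len(metabolites), len(reaction_ids)))
    met_index = {mid: i for i, mid in enumerate(metabolites)}
    for j, rid in enumerate(reaction_ids):
        for mid, coeff in columns[rid].items():
            S[met_index[mid], j] = coeff
    weights = np.array([1.0 if rid == "BIOMASS" else 0.0 for rid in reaction_ids])

    net = MetabolicNetwork(
        reaction_ids=reaction_ids,
        metabolite_ids=metabolites,
        stoichiometry=S,
        lower_bounds=np.array([bounds[r][0] for r in reaction_ids]),
        upper_bounds=np.array([bounds[r][1] for r in reaction_ids]),
        objective_weights=weights,
        exchange_map={
            "glucose": "EX_glc" if "glucose" in cfg.substrates else None,
            "xylose": "EX_xyl" if "xylose" in cfg.substrates else None,
            "ethanol": "EX_etoh",
            "oxygen": "EX_o2",
        },
        compartment_of=compartment,
        maintenance_reaction_id="ATPM",
    )
    if params is None:
        try:
            params = table_params(label)
        except KeyError:
            # generic magnitudes for ad-hoc labels; capabilities follow the
            # included substrates
            params = UptakeParams(
                v_g_max=10.0, K_g=0.5, K_ieg=10.0,
                v_z_max=5.0 if "xylose" in cfg.substrates else None,
                K_z=0.25 if "xylose" in cfg.substrates else None,
                K_igz=0.5 if "xylose" in cfg.substrates else None,
                K_iez=4.5 if "xylose" in cfg.substrates else None,
                v_o_max=10.0, K_o=0.0125,
            )
    return SpeciesModel(label=label, network=net, uptake=params, knockouts=knockouts)


def make_toy_community(
    cfg_cerevisiae: ToyNetworkConfig | None = None,
    cfg_stipitis: ToyNetworkConfig | None = None,
    params_cerevisiae: UptakeParams | None = None,
    params_stipitis: UptakeParams | None = None,
    context: str = "co_culture",
) -> list[SpeciesModel]:
    """Default two-member toy co-culture.

    A glucose-only cerevisiae-like member with its respiration knocked out
    (the respiratory-deficient strain) and a glucose+xylose stipitis-like
    member with diauxic kinetics.  Transport parameters default to the
    published values for the requested context.
    """
    cfg_c = cfg_cerevisiae or ToyNetworkConfig(substrates=("glucose",))
    cfg_s = cfg_stipitis or ToyNetworkConfig(substrates=("glucose", "xylose"))
    cerevisiae = make_toy_species(
        cfg_c,
        label="cerevisiae",
        params=params_cerevisiae or table_params("cerevisiae", context),
        knockouts=("RESP",),
    )
    stipitis = make_toy_species(
        cfg_s,
        label="stipitis",
        params=params_stipitis or table_params("stipitis", context),
    )
    return [cerevisiae, stipitis]


def community_of(models: list[SpeciesModel]) -> CommunityNetwork:
    """Block-diagonal community of the members' knockout-applied networks."""
    return combine_networks(
        [(m.label, m.effective_network()) for m in models]
    )


def generate_batch_profiles(models, cond, noise: NoiseSpec):
    """Simulate a batch and sample noisy concentration series from it.

    Returns a :class:`~dfba_coculture.calibration.BatchDataset` whose
    metadata records the run conditions and the generating ("ground
    truth") uptake parameters, so calibration tests can score recovery.
    Noise is multiplicative Gaussian per series, clipped at zero, fully
    determined by ``noise.seed``.
    """
    from .calibration import BatchDataset
    from .dfba_engine import simulate_batch

    result = simulate_batch(models, cond)
    traj = result.trajectory
    t_max = float(traj["time_h"].iloc[-1])
    times = np.arange(0.0, t_max + 1e-9, noise.interval)
    series_cols = {
        "glucose": "glucose_g_L",
        "xylose": "xylose_g_L",
        "ethanol": "ethanol_g_L",
        "biomass_cerevisiae": "X_cerevisiae_gdw_L",
        "biomass_stipitis": "X_stipitis_gdw_L",
        "oxygen": "DO_mM",
    }
    rng = np.random.default_rng(noise.seed)
    series = {}
    for name, col in series_cols.items():
        clean = np.interp(times, traj["time_h"].to_numpy(), traj[col].to_numpy())
        if np.all(clean == 0):
            continue
        noisy = clean * (1.0 + noise.level * rng.standard_normal(len(times)))
        series[name] = np.clip(noisy, 0.0, None)
    metadata = {
        "kla": cond.kla,
        "o_star": cond.o_star,
        "context": cond.context,
        "initial": cond.initial.to_dict(),
        "t_end": cond.t_end,
        "noise_level": noise.level,
        "seed": noise.seed,
        "ground_truth": {m.label: m.uptake.to_dict() for m in models},
    }
    return BatchDataset(time=times, series=series, metadata=metadata)


def bruteforce_lp(
    community: CommunityNetwork | MetabolicNetwork,
    uptake_bounds: dict[str, dict[str, float]] | None = None,
    *,
    extra_bounds: dict[str, dict[str, tuple[float, float]]] | None = None,
    max_reactions: int = 12,
) -> FluxSolution:
    """Exhaustive vertex-enumeration oracle for small flux balance LPs.

    Enumerates all basic solutions (every choice of basis columns with the
    nonbasic fluxes pinned at either bound) of each member's LP and keeps
    the feasible vertex with the largest growth rate.  Because the
    community matrix is block diagonal and caps are per-member, members
    are enumerated independently and their optima summed.  Refuses
    networks with more than ``max_reactions`` reactions (the enumeration
    is exponential).  Testing oracle only — never used by the simulator.
    """
    if isinstance(community, MetabolicNetwork):
        community = combine_networks([("only", community)])
    from .metabolic_network import _assemble_bounds

    lb_all, ub_all = _assemble_bounds(community, uptake_bounds, extra_bounds)
    members: dict[str, MemberFluxes] = {}
    for label, net in community.members:
        if net.n_reactions > max_reactions:
            raise ValueError(
                f"member {label!r} has {net.n_reactions} reactions; the "
                f"enumeration oracle refuses more than {max_reactions}"
            )
        sl = community.reaction_slices[label]
        best = _bruteforce_member(
            net.stoichiometry, lb_all[sl], ub_all[sl], net.objective_weights
        )
        if best is None:
            return FluxSolution(status="infeasible")
        v = best
        exchange = {
            species: (float(v[net.index(rxn)]) if rxn else 0.0)
            for species, rxn in net.exchange_map.items()
        }
        members[label] = MemberFluxes(
            mu=float(net.objective_weights @ v),
            exchange=exchange,
            fluxes=v,
            residual=float(np.abs(net.stoichiometry @ v).max()),
        )
    objective = sum(m.mu for m in members.values())
    return FluxSolution(status="optimal", objective=objective, members=members)


def _bruteforce_member(S, lb, ub, w, feas_tol=1e-9):
    """Best feasible basic solution of max w.v s.t. S v = 0, lb <= v <= ub."""
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if m else 0
    best_obj, best_v = -np.inf, None
    cols = range(n)
    for basis in itertools.combinations(cols, rank):
        B = S[:, basis]
        if rank and np.linalg.matrix_rank(B) < rank:
            continue
        nonbasic = [j for j in cols if j not in basis]
        for assignment in itertools.product((0, 1), repeat=len(nonbasic)):
            v = np.empty(n)
            for j, side in zip(nonbasic, assignment):
                v[j] = lb[j] if side == 0 else ub[j]
            rhs = -S[:, nonbasic] @ v[nonbasic] if nonbasic else np.zeros(m)
            if rank:
                sol, res, rk, _ = np.linalg.lstsq(B, rhs, rcond=None)
                if np.abs(B @ sol - rhs).max() > feas_tol:
                    continue
                v[list(basis)] = sol
            if np.any(v < lb - feas_tol) or np.any(v > ub + feas_tol):
                continue
            obj = float(w @ v)
            if obj > best_obj:
                best_obj, best_v = obj, v.copy()
    return best_v


def random_toy_problem(rng: np.random.Generator):
    """Random small network + caps for oracle-equivalence checks.

    Draws yields, maintenance and uptake caps from wide ranges while
    preserving the fermentation-below-respiration structure; occasionally
    includes the xylose or ethanol routes.  Returns ``(SpeciesModel,
    uptake_caps_dict)``.
    """
    substrates = ["glucose"]
    if rng.random() < 0.5:
        substrates.append("xylose")
    elif rng.random() < 0.3:
        substrates.append("ethanol")
    cfg = ToyNetworkConfig(
        substrates=tuple(substrates),
        atp_per_glucose_ferm=float(rng.uniform(1.0, 4.0)),
        ethanol_per_glucose=float(rng.uniform(1.0, 2.0)),
        atp_per_glucose_resp=float(rng.uniform(15.0, 30.0)),
        o2_per_glucose_resp=float(rng.uniform(4.0, 8.0)),
        atp_per_xylose=float(rng.uniform(2.0, 8.0)),
        o2_per_xylose=float(rng.uniform(0.2, 1.5)),
        ethanol_per_xylose=float(rng.uniform(0.5, 2.0)),
        atp_per_ethanol=float(rng.uniform(6.0, 15.0)),
        o2_per_ethanol=float(rng.uniform(2.0, 4.0)),
        atp_per_biomass=float(rng.uniform(50.0, 150.0)),
        maintenance=float(rng.uniform(0.0, 3.0)),
    )
    model = make_toy_species(cfg, label="toy")
    caps = {
        "glucose": float(rng.uniform(0.0, 20.0)),
        "xylose": float(rng.uniform(0.0, 8.0)),
        "ethanol": float(rng.uniform(0.0, 10.0)) if "ethanol" in substrates else 0.0,
        "oxygen": float(rng.uniform(0.0, 15.0)),
    }
    return model, caps
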
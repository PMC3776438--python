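"""Stoichiometric networks and the community flux balance LP.

A :class:`MetabolicNetwork` is a metabolite-by-reaction stoichiometric
matrix with flux bounds and biomass objective weights.  Networks of
different species are assembled block-diagonally into a
:class:`CommunityNetwork`; the community LP maximizes the *sum* of the
members' growth rates subject to per-member steady-state mass balance and
flux bounds — each species grows as fast as its own constraints allow and
the only coupling between species is through the shared extracellular
substrate pools, which enter as kinetic caps on the mapped exchange
reactions.

Uptake is a negative exchange flux throughout.  Among alternate optima the
reported solution is made unique by a secondary LP that minimizes the sum
of absolute fluxes at the fixed optimal growth rate (parsimonious FBA),
so the exchange fluxes handed to the dynamic layer are reproducible.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import swiglpk as glp

from .uptake_kinetics import UptakeParams

EXCHANGE_SPECIES = ("glucose", "xylose", "ethanol", "oxygen")

#: feasibility/optimality tolerance used on hand-sized networks
TOY_TOL = 1e-9
#: tolerance recommended for genome-scale reconstructions
GENOME_TOL = 1e-7


class ModelError(ValueError):
    """The file or network is not a usable flux balance model."""


class ConfigurationError(ValueError):
    """Ambiguous or inconsistent user configuration."""


class SolverError(RuntimeError):
    """Numerical failure of the LP solver (distinct from infeasibility)."""


@dataclass
class MetabolicNetwork:
    """Stoichiometric model of one species.

    Attributes
    ----------
    reaction_ids, metabolite_ids:
        Unique identifiers; their order fixes the matrix columns/rows.
    stoichiometry:
        Dense (n_metabolites, n_reactions) coefficient matrix.
    lower_bounds, upper_bounds:
        Flux bounds, mmol/gdw/h.
    objective_weights:
        Biomass contribution of each reaction; the growth rate is
        ``objective_weights @ fluxes``.
    exchange_map:
        Maps each extracellular species in :data:`EXCHANGE_SPECIES` to the
        reaction id of its exchange reaction, or ``None`` when the species
        has no such exchange (e.g. no xylose exchange for S. cerevisiae).
    compartment_of:
        Reaction id -> compartment label (``cytoplasm`` / ``mitochondria``
        / ``extracellular``).
    maintenance_reaction_id:
        Id of the non-growth-associated ATP maintenance reaction, if any.
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]
    stoichiometry: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    objective_weights: np.ndarray
    exchange_map: dict[str, str | None] = field(default_factory=dict)
    compartment_of: dict[str, str] = field(default_factory=dict)
    maintenance_reaction_id: str | None = None

    def __post_init__(self) -> None:
        self.stoichiometry = np.asarray(self.stoichiometry, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.objective_weights = np.asarray(self.objective_weights, dtype=float)
        m, n = len(self.metabolite_ids), len(self.reaction_ids)
        if len(set(self.reaction_ids)) != n or len(set(self.metabolite_ids)) != m:
            raise ModelError("duplicate reaction or metabolite identifiers")
        if self.stoichiometry.shape != (m, n):
            raise ModelError(
                f"stoichiometry shape {self.stoichiometry.shape} != ({m}, {n})"
            )
        for arr, name in (
            (self.lower_bounds, "lower_bounds"),
            (self.upper_bounds, "upper_bounds"),
            (self.objective_weights, "objective_weights"),
        ):
            if arr.shape != (n,):
                raise ModelError(f"{name} must have one entry per reaction")
        if np.any(self.lower_bounds > self.upper_bounds):
            raise ModelError("lower_bounds exceed upper_bounds")
        known = set(self.reaction_ids)
        for species, rxn in self.exchange_map.items():
            if rxn is not None and rxn not in known:
                raise ModelError(f"exchange reaction {rxn!r} ({species}) unknown")
        if (
            self.maintenance_reaction_id is not None
            and self.maintenance_reaction_id not in known
        ):
            raise ModelError(
                f"maintenance reaction {self.maintenance_reaction_id!r} unknown"
            )
        self._index = {rid: j for j, rid in enumerate(self.reaction_ids)}

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def index(self, reaction_id: str) -> int:
        try:
            return self._index[reaction_id]
        except KeyError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            stoichiometry=self.stoichiometry.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            objective_weights=self.objective_weights.copy(),
            exchange_map=dict(self.exchange_map),
            compartment_of=dict(self.compartment_of),
            maintenance_reaction_id=self.maintenance_reaction_id,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            self.reaction_ids == other.reaction_ids
            and self.metabolite_ids == other.metabolite_ids
            and np.array_equal(self.stoichiometry, other.stoichiometry)
            and np.array_equal(self.lower_bounds, other.lower_bounds)
            and np.array_equal(self.upper_bounds, other.upper_bounds)
            and np.array_equal(self.objective_weights, other.objective_weights)
            and self.exchange_map == other.exchange_map
            and self.maintenance_reaction_id == other.maintenance_reaction_id
        )


@dataclass
class SpeciesModel:
    """A species network with its uptake kinetics and knockout set."""

    label: str
    network: MetabolicNetwork
    uptake: UptakeParams
    knockouts: tuple[str, ...] = ()

    def effective_network(self) -> MetabolicNetwork:
        """Network with the knockouts applied (both bounds zeroed)."""
        if not self.knockouts:
            return self.network
        return apply_knockouts(self.network, list(self.knockouts))

    def with_uptake(self, uptake: UptakeParams) -> "SpeciesModel":
        return SpeciesModel(self.label, self.network, uptake, self.knockouts)


@dataclass
class CommunityNetwork:
    """Block-diagonal assembly of member networks (no cross-member coupling)."""

    members: list[tuple[str, MetabolicNetwork]]
    reaction_slices: dict[str, slice] = field(init=False)
    metabolite_slices: dict[str, slice] = field(init=False)

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.members]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"duplicate species labels in {labels}")
        if not self.members:
            raise ConfigurationError("community needs at least one member")
        self.reaction_slices = {}
        self.metabolite_slices = {}
        r = m = 0
        for label, net in self.members:
            self.reaction_slices[label] = slice(r, r + net.n_reactions)
            self.metabolite_slices[label] = slice(m, m + net.n_metabolites)
            r += net.n_reactions
            m += net.n_metabolites

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.members]

    def member(self, label: str) -> MetabolicNetwork:
        for lab, net in self.members:
            if lab == label:
                return net
        raise KeyError(label)

    def combined_stoichiometry(self) -> np.ndarray:
        """The block-diagonal community matrix."""
        n = sum(net.n_reactions for _, net in self.members)
        m = sum(net.n_metabolites for _, net in self.members)
        A = np.zeros((m, n))
        for label, net in self.members:
            A[self.metabolite_slices[label], self.reaction_slices[label]] = (
                net.stoichiometry
            )
        return A

    def combined_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.concatenate([net.lower_bounds for _, net in self.members])
        ub = np.concatenate([net.upper_bounds for _, net in self.members])
        return lb, ub

    def combined_objective(self) -> np.ndarray:
        return np.concatenate([net.objective_weights for _, net in self.members])


@dataclass
class MemberFluxes:
    """Per-species slice of a community flux solution."""

    mu: float
    exchange: dict[str, float]
    fluxes: np.ndarray
    residual: float


@dataclass
class FluxSolution:
    """Result of the community LP.

    ``status`` is ``"optimal"`` or ``"infeasible"``; only optimal solutions
    carry fluxes.  ``objective`` is the community growth rate, equal to the
    sum of the members' ``mu`` within solver tolerance.
    """

    status: str
    objective: float | None = None
    members: dict[str, MemberFluxes] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    @property
    def residual(self) -> float:
        return max((m.residual for m in self.members.values()), default=0.0)


@dataclass(frozen=True)
class PhenotypeCriteria:
    """Directional phenotype targets for the knockout screen, vs. wild type."""

    biomass_yield_direction: str = "lower"
    ethanol_yield_direction: str = "higher"
    oxygen_demand_direction: str = "lower"
    growth_on_nonfermentable_substrates: bool = False

    def __post_init__(self) -> None:
        for name in (
            "biomass_yield_direction",
            "ethanol_yield_direction",
            "oxygen_demand_direction",
        ):
            if getattr(self, name) not in ("lower", "higher"):
                raise ConfigurationError(f"{name} must be 'lower' or 'higher'")


def apply_knockouts(
    net: MetabolicNetwork, knockout_ids: list[str]
) -> MetabolicNetwork:
    """Return a copy of ``net`` with both bounds of each reaction set to zero."""
    out = net.copy()
    for rid in knockout_ids:
        j = out.index(rid)
        out.lower_bounds[j] = 0.0
        out.upper_bounds[j] = 0.0
    return out


def combine_networks(
    members: list[tuple[str, MetabolicNetwork]] | dict[str, MetabolicNetwork],
) -> CommunityNetwork:
    """Assemble labelled member networks into a block-diagonal community."""
    if isinstance(members, dict):
        members = list(members.items())
    return CommunityNetwork(members=[(label, net) for label, net in members])


def _assemble_bounds(
    community: CommunityNetwork,
    uptake_bounds: dict[str, dict[str, float]] | None,
    extra_bounds: dict[str, dict[str, tuple[float, float]]] | None,
) -> tuple[np.ndarray, np.ndarray]:
    lb, ub = community.combined_bounds()
    lb, ub = lb.copy(), ub.copy()
    for label, net in community.members:
        offset = community.reaction_slices[label].start
        caps = (uptake_bounds or {}).get(label)
        if caps is not None:
            for species, cap in caps.items():
                if cap < 0:
                    raise ValueError(f"uptake cap {species}={cap} must be >= 0")
                rxn = net.exchange_map.get(species)
                if rxn is None:
                    continue
                lb[offset + net.index(rxn)] = -cap
        overrides = (extra_bounds or {}).get(label)
        if overrides is not None:
            for rxn, (lo, hi) in overrides.items():
                j = offset + net.index(rxn)
                lb[j], ub[j] = lo, hi
    if np.any(lb > ub):
        raise ValueError("assembled lower bounds exceed upper bounds")
    return lb, ub


def _extract(community, x, tol):
    members = {}
    for label, net in community.members:
        v = x[community.reaction_slices[label]]
        exchange = {}
        for species in EXCHANGE_SPECIES:
            rxn = net.exchange_map.get(species)
            exchange[species] = float(v[net.index(rxn)]) if rxn else 0.0
        residual = float(np.abs(net.stoichiometry @ v).max()) if net.n_metabolites else 0.0
        members[label] = MemberFluxes(
            mu=float(net.objective_weights @ v),
            exchange=exchange,
            fluxes=v.copy(),
            residual=residual,
        )
    objective = sum(m.mu for m in members.values())
    return FluxSolution(status="optimal", objective=objective, members=members)


glp.glp_term_out(glp.GLP_OFF)

_GLP_BIG = 1e30  # bounds at or beyond this magnitude are treated as free


class CommunityLP:
    """Persistent LP for one community, re-solved under changing bounds.

    The problem is built once in GLPK and kept alive; every call updates
    the flux bounds in place and re-solves with the previous basis as a
    warm start, which makes the thousands of solves inside a batch
    integration cheap.  The layout is

    * columns: the n community fluxes v, then n auxiliaries a >= |v|;
    * rows: the metabolite balances (fixed at 0), the growth row w.v
      (free during the primary solve, pinned at the optimum during the
      parsimony pass), and the 2n rows a - v >= 0, a + v >= 0.

    The primary pass maximizes w.v; the parsimony pass fixes w.v = mu*
    and minimizes sum(a), making the reported flux vector unique among
    alternate optima.
    """

    def __init__(self, community: CommunityNetwork | MetabolicNetwork):
        if isinstance(community, MetabolicNetwork):
            community = combine_networks([("only", community)])
        self.community = community
        self.w = community.combined_objective()
        n = self.n = len(self.w)
        A = community.combined_stoichiometry()
        m = self.m = A.shape[0]

        prob = self.prob = glp.glp_create_prob()
        glp.glp_add_rows(prob, m + 1 + 2 * n)
        glp.glp_add_cols(prob, 2 * n)
        for i in range(1, m + 1):
            glp.glp_set_row_bnds(prob, i, glp.GLP_FX, 0.0, 0.0)
        self._mu_row = m + 1
        glp.glp_set_row_bnds(prob, self._mu_row, glp.GLP_FR, 0.0, 0.0)
        for j in range(n):  # a_j - v_j >= 0 and a_j + v_j >= 0
            glp.glp_set_row_bnds(prob, m + 2 + 2 * j, glp.GLP_LO, 0.0, 0.0)
            glp.glp_set_row_bnds(prob, m + 3 + 2 * j, glp.GLP_LO, 0.0, 0.0)
        for j in range(n):
            glp.glp_set_col_bnds(prob, n + 1 + j, glp.GLP_LO, 0.0, 0.0)

        entries = []
        rows, cols = np.nonzero(A)
        for i, j in zip(rows, cols):
            entries.append((int(i) + 1, int(j) + 1, float(A[i, j])))
        for j in range(n):
            if self.w[j] != 0.0:
                entries.append((self._mu_row, j + 1, float(self.w[j])))
            entries.append((m + 2 + 2 * j, j + 1, -1.0))
            entries.append((m + 2 + 2 * j, n + 1 + j, 1.0))
            entries.append((m + 3 + 2 * j, j + 1, 1.0))
            entries.append((m + 3 + 2 * j, n + 1 + j, 1.0))
        nnz = len(entries)
        ia, ja = glp.intArray(nnz + 1), glp.intArray(nnz + 1)
        ar = glp.doubleArray(nnz + 1)
        for k, (i, j, val) in enumerate(entries, start=1):
            ia[k], ja[k], ar[k] = i, j, val
        glp.glp_load_matrix(prob, nnz, ia, ja, ar)

        self.params = glp.glp_smcp()
        glp.glp_init_smcp(self.params)
        self.params.msg_lev = glp.GLP_MSG_OFF
        self.params.tol_bnd = 1e-10
        self.params.tol_dj = 1e-10
        glp.glp_std_basis(prob)

    def __del__(self):  # pragma: no cover - interpreter shutdown ordering
        try:
            glp.glp_delete_prob(self.prob)
        except Exception:
            pass

    def _set_flux_bounds(self, lb: np.ndarray, ub: np.ndarray) -> None:
        for j in range(self.n):
            lo, hi = lb[j], ub[j]
            free_lo, free_hi = lo <= -_GLP_BIG, hi >= _GLP_BIG
            if free_lo and free_hi:
                glp.glp_set_col_bnds(self.prob, j + 1, glp.GLP_FR, 0.0, 0.0)
            elif free_lo:
                glp.glp_set_col_bnds(self.prob, j + 1, glp.GLP_UP, 0.0, hi)
            elif free_hi:
                glp.glp_set_col_bnds(self.prob, j + 1, glp.GLP_LO, lo, 0.0)
            elif lo == hi:
                glp.glp_set_col_bnds(self.prob, j + 1, glp.GLP_FX, lo, hi)
            else:
                glp.glp_set_col_bnds(self.prob, j + 1, glp.GLP_DB, lo, hi)

    def _set_objective(self, maximize_growth: bool) -> None:
        if maximize_growth:
            glp.glp_set_obj_dir(self.prob, glp.GLP_MAX)
            for j in range(self.n):
                glp.glp_set_obj_coef(self.prob, j + 1, float(self.w[j]))
                glp.glp_set_obj_coef(self.prob, self.n + 1 + j, 0.0)
        else:
            glp.glp_set_obj_dir(self.prob, glp.GLP_MIN)
            for j in range(self.n):
                glp.glp_set_obj_coef(self.prob, j + 1, 0.0)
                glp.glp_set_obj_coef(self.prob, self.n + 1 + j, 1.0)

    def _simplex(self) -> str:
        ret = glp.glp_simplex(self.prob, self.params)
        if ret != 0:  # warm basis went stale; retry cold once
            glp.glp_std_basis(self.prob)
            ret = glp.glp_simplex(self.prob, self.params)
            if ret != 0:
                raise SolverError(f"GLPK simplex failed with code {ret}")
        status = glp.glp_get_status(self.prob)
        if status == glp.GLP_OPT:
            return "optimal"
        if status in (glp.GLP_NOFEAS, glp.GLP_INFEAS):
            return "infeasible"
        if status == glp.GLP_UNBND:
            raise SolverError("LP is unbounded")
        raise SolverError(f"unexpected GLPK status {status}")

    def solve(
        self,
        uptake_bounds: dict[str, dict[str, float]] | None = None,
        extra_bounds: dict[str, dict[str, tuple[float, float]]] | None = None,
        parsimonious: bool = True,
        tol: float = TOY_TOL,
    ) -> FluxSolution:
        lb, ub = _assemble_bounds(self.community, uptake_bounds, extra_bounds)
        self._set_flux_bounds(lb, ub)
        glp.glp_set_row_bnds(self.prob, self._mu_row, glp.GLP_FR, 0.0, 0.0)
        self._set_objective(maximize_growth=True)
        status = self._simplex()
        if status != "optimal":
            return FluxSolution(status="infeasible")
        x = np.array(
            [glp.glp_get_col_prim(self.prob, j + 1) for j in range(self.n)]
        )
        if not parsimonious:
            return _extract(self.community, x, tol)
        mu_star = float(self.w @ x)
        glp.glp_set_row_bnds(self.prob, self._mu_row, glp.GLP_FX, mu_star, mu_star)
        self._set_objective(maximize_growth=False)
        try:
            status = self._simplex()
        except SolverError:
            status = "failed"
        if status != "optimal":
            # keep the primary solution rather than fail the step
            return _extract(self.community, x, tol)
        x2 = np.array(
            [glp.glp_get_col_prim(self.prob, j + 1) for j in range(self.n)]
        )
        return _extract(self.community, x2, tol)


def solve_community_fba(
    community: CommunityNetwork | MetabolicNetwork,
    uptake_bounds: dict[str, dict[str, float]] | None = None,
    *,
    extra_bounds: dict[str, dict[str, tuple[float, float]]] | None = None,
    parsimonious: bool = True,
    tol: float = TOY_TOL,
) -> FluxSolution:
    """Maximize the summed growth rate of all community members.

    Parameters
    ----------
    community:
        A :class:`CommunityNetwork` (a bare network is wrapped as a
        single-member community labelled ``"only"``).
    uptake_bounds:
        ``{label: {species: cap}}`` nonnegative exchange-flux magnitudes;
        each cap sets the lower bound of the mapped exchange reaction to
        ``-cap``.  Species without the exchange are silently skipped.
    extra_bounds:
        ``{label: {reaction_id: (lb, ub)}}`` explicit bound overrides,
        applied after the caps (used e.g. for the maintenance toggle).
    parsimonious:
        Resolve alternate optima by minimizing the sum of absolute fluxes
        at the fixed optimal growth rate.

    Returns
    -------
    FluxSolution with ``status`` ``"optimal"`` or ``"infeasible"``.
    Solver breakdowns raise :class:`SolverError` instead.

    Repeated solves of the same community under changing bounds should go
    through a cached :class:`CommunityLP` instead (this helper rebuilds
    the problem every call).
    """
    return CommunityLP(community).solve(
        uptake_bounds, extra_bounds, parsimonious=parsimonious, tol=tol
    )


def solve_fba(
    net: MetabolicNetwork,
    uptake_bounds: dict[str, float] | None = None,
    **kwargs,
) -> FluxSolution:
    """Single-species FBA; caps are keyed by extracellular species only."""
    community = combine_networks([("only", net)])
    wrapped = {"only": uptake_bounds} if uptake_bounds else None
    return solve_community_fba(community, wrapped, **kwargs)


def _yields(sol: FluxSolution) -> tuple[float, float, float, float]:
    m = sol.members["only"]
    g_uptake = max(-m.exchange["glucose"], 0.0)
    if g_uptake <= 0:
        return 0.0, 0.0, abs(m.exchange["oxygen"]), m.mu
    return (
        m.mu / g_uptake,
        max(m.exchange["ethanol"], 0.0) / g_uptake,
        abs(m.exchange["oxygen"]),
        m.mu,
    )


def screen_respiratory_knockouts(
    net: MetabolicNetwork,
    criteria: PhenotypeCriteria,
    reference: FluxSolution,
    *,
    medium: dict[str, float],
    nonfermentable_medium: dict[str, float] | None = None,
    include_pairs: bool = True,
    tol: float = 1e-6,
) -> list[tuple[str, ...]]:
    """Enumerate mitochondrial knockouts reproducing a respiratory-deficient
    phenotype.

    Single (and optionally paired) knockouts among reactions labelled
    ``mitochondria`` are applied one set at a time; a set is accepted when
    its FBA phenotype on ``medium`` moves in the required direction for
    every criterion relative to ``reference`` (biomass yield = growth per
    glucose uptake, ethanol yield = ethanol secretion per glucose uptake,
    oxygen demand = oxygen uptake magnitude), and, when
    ``growth_on_nonfermentable_substrates`` is False and a
    ``nonfermentable_medium`` is supplied, shows no growth on it.

    Returns the accepted knockout sets in deterministic (sorted) order.
    """
    mito = sorted(
        rid for rid in net.reaction_ids
        if net.compartment_of.get(rid) == "mitochondria"
    )
    if not mito:
        raise ConfigurationError("network has no mitochondrial reactions")
    if not reference.optimal:
        raise ValueError("reference solution must be optimal")
    ref_by, ref_ey, ref_o2, _ = _yields(reference)

    candidates: list[tuple[str, ...]] = [(r,) for r in mito]
    if include_pairs:
        candidates += [tuple(pair) for pair in itertools.combinations(mito, 2)]

    def direction_ok(value: float, ref: float, direction: str) -> bool:
        return value < ref - tol if direction == "lower" else value > ref + tol

    accepted = []
    for ko in candidates:
        sol = solve_fba(apply_knockouts(net, list(ko)), dict(medium))
        if not sol.optimal:
            continue
        by, ey, o2, _ = _yields(sol)
        if not direction_ok(by, ref_by, criteria.biomass_yield_direction):
            continue
        if not direction_ok(ey, ref_ey, criteria.ethanol_yield_direction):
            continue
        if not direction_ok(o2, ref_o2, criteria.oxygen_demand_direction):
            continue
        if (
            not criteria.growth_on_nonfermentable_substrates
            and nonfermentable_medium is not None
        ):
            nf = solve_fba(apply_knockouts(net, list(ko)), dict(nonfermentable_medium))
            if nf.optimal and nf.objective > tol:
                continue
        accepted.append(ko)
    return accepted


# ---------------------------------------------------------------------------
# SBML input/output (through cobrapy)

_EXCHANGE_PATTERNS = {
    "glucose": ("glc__d", "glc_d", "glc-d", "glc", "glucose"),
    "xylose": ("xyl__d", "xyl_d", "xyl-d", "xyl", "xylose"),
    "ethanol": ("etoh", "ethanol"),
    "oxygen": ("o2", "oxygen"),
}

_MITO_HINTS = ("m", "mm", "mito", "mitochondria", "mitochondrion")
_EXTRA_HINTS = ("e", "ext", "extracellular", "external", "boundary")


def _compartment_label(compartments: set[str], names: dict[str, str]) -> str:
    labels = set()
    for cid in compartments:
        name = (names.get(cid) or "").lower()
        key = cid.lower()
        if key in _MITO_HINTS or "mito" in name:
            labels.add("mitochondria")
        elif key in _EXTRA_HINTS or "extracell" in name:
            labels.add("extracellular")
        else:
            labels.add("cytoplasm")
    if "mitochondria" in labels:
        return "mitochondria"
    if labels == {"extracellular"}:
        return "extracellular"
    return "cytoplasm"


def load_sbml(
    path: str,
    exchange_overrides: dict[str, str | None] | None = None,
) -> MetabolicNetwork:
    """Read an SBML model into a :class:`MetabolicNetwork`.

    The exchange map is resolved by matching extracellular metabolite
    identifiers/names for glucose, xylose, ethanol and oxygen against
    common conventions; unresolved species are recorded as ``None``.
    An ambiguous match raises :class:`ConfigurationError` unless an
    explicit ``exchange_overrides`` entry decides it.
    """
    import cobra
    from cobra.util.array import create_stoichiometric_matrix

    try:
        model = cobra.io.read_sbml_model(path)
    except Exception as exc:  # cobra raises a mix of IO/parse errors
        raise ModelError(f"could not parse SBML file {path!r}: {exc}") from exc

    weights = np.array(
        [r.objective_coefficient for r in model.reactions], dtype=float
    )
    if not np.any(weights):
        raise ModelError(f"no objective reaction found in {path!r}")

    S = create_stoichiometric_matrix(model)
    reaction_ids = [r.id for r in model.reactions]
    metabolite_ids = [m.id for m in model.metabolites]
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)

    compartment_names = dict(model.compartments)
    compartment_of = {}
    for r in model.reactions:
        note = (r.notes or {}).get("compartment")
        if note:
            compartment_of[r.id] = str(note)
        else:
            compartment_of[r.id] = _compartment_label(
                {m.compartment for m in r.metabolites if m.compartment},
                compartment_names,
            )

    exchange_map: dict[str, str | None] = {}
    overrides = exchange_overrides or {}
    boundary = [r for r in model.reactions if r.boundary]
    for species, patterns in _EXCHANGE_PATTERNS.items():
        if species in overrides:
            exchange_map[species] = overrides[species]
            continue
        matches = []
        for r in boundary:
            if len(r.metabolites) != 1:
                continue
            met = next(iter(r.metabolites))
            key = met.id.lower()
            name_tokens = set(re.split(r"[^a-z0-9]+", (met.name or "").lower()))
            stem = key.rsplit("_", 1)[0] if "_" in key else key
            if any(
                stem == p or p in name_tokens or key.startswith(p + "_")
                for p in patterns
            ):
                matches.append(r.id)
        if len(matches) > 1:
            raise ConfigurationError(
                f"ambiguous exchange match for {species}: {sorted(matches)}; "
                "pass an explicit exchange_overrides mapping"
            )
        exchange_map[species] = matches[0] if matches else None

    maintenance = None
    for r in model.reactions:
        if r.id.upper() in ("ATPM", "MAINT") or "maintenance" in (r.name or "").lower():
            maintenance = r.id
            break

    return MetabolicNetwork(
        reaction_ids=reaction_ids,
        metabolite_ids=metabolite_ids,
        stoichiometry=S,
        lower_bounds=lb,
        upper_bounds=ub,
        objective_weights=weights,
        exchange_map=exchange_map,
        compartment_of=compartment_of,
        maintenance_reaction_id=maintenance,
    )


_METABOLITE_NAMES = {
    "glc_e": "D-Glucose",
    "xyl_e": "D-Xylose",
    "etoh_e": "Ethanol",
    "o2_e": "Oxygen",
    "atp_c": "ATP",
}


def to_cobra(net: MetabolicNetwork, model_id: str = "model"):
    """Convert to a cobra model (used for SBML export of toy networks)."""
    import cobra

    model = cobra.Model(model_id)
    model.compartments = {"c": "cytoplasm", "e": "extracellular", "m": "mitochondria"}
    mets = {}
    for mid in net.metabolite_ids:
        compartment = mid.rsplit("_", 1)[-1] if "_" in mid else "c"
        if compartment not in ("c", "e", "m"):
            compartment = "c"
        met = cobra.Metabolite(
            mid, name=_METABOLITE_NAMES.get(mid, mid), compartment=compartment
        )
        mets[mid] = met
    model.add_metabolites(list(mets.values()))
    reactions = []
    for j, rid in enumerate(net.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(net.lower_bounds[j])
        rxn.upper_bound = float(net.upper_bounds[j])
        coeffs = {
            mets[net.metabolite_ids[i]]: float(net.stoichiometry[i, j])
            for i in range(net.n_metabolites)
            if net.stoichiometry[i, j] != 0
        }
        rxn.add_metabolites(coeffs)
        label = net.compartment_of.get(rid)
        if label:
            rxn.notes["compartment"] = label
        reactions.append(rxn)
    model.add_reactions(reactions)
    objective = {
        model.reactions.get_by_id(rid): float(net.objective_weights[j])
        for j, rid in enumerate(net.reaction_ids)
        if net.objective_weights[j] != 0
    }
    from cobra.util.solver import set_objective

    set_objective(model, objective)
    return model


def write_sbml(net: MetabolicNetwork, path: str, model_id: str = "model") -> None:
    """Write a network to SBML (round-trips through :func:`load_sbml`)."""
    import cobra

    cobra.io.write_sbml_model(to_cobra(net, model_id), path)
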
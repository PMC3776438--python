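"""Kinetic caps on substrate exchange fluxes.

Sugar and oxygen uptake rates are not free variables of the flux balance
problem: at every instant they are capped by Michaelis-Menten expressions
evaluated on the extracellular concentrations.  Glucose uptake is inhibited
by ethanol; xylose uptake is additionally repressed by glucose (the diauxic
term) and inhibited by ethanol; oxygen uptake depends only on dissolved
oxygen.  The resulting magnitudes become lower bounds (uptake is negative)
on the mapped exchange reactions of the community LP.

Units follow the fermentation literature: sugars and ethanol in g/L,
dissolved oxygen in mM, uptake rates in mmol/gdw/h.  No unit conversion
happens inside this module.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass


@dataclass(frozen=True)
class UptakeParams:
    """Per-species transport parameters.

    ``None`` encodes an absent capability: a species with ``v_z_max=None``
    has no xylose transport system and its xylose uptake bound is
    identically zero.  All present values must be strictly positive
    (``math.inf`` is allowed for inhibition constants, which turns the
    corresponding inhibition factor off).

    Attributes
    ----------
    v_g_max, v_z_max, v_o_max:
        Maximum glucose / xylose / oxygen uptake rates, mmol/gdw/h.
    K_g, K_z:
        Sugar saturation constants, g/L.
    K_o:
        Oxygen saturation constant, mM.
    K_ieg, K_iez:
        Ethanol inhibition constants for glucose and xylose uptake, g/L.
    K_igz:
        Glucose inhibition (catabolite repression) constant for xylose
        uptake, g/L.
    """

    v_g_max: float | None = None
    K_g: float | None = None
    K_ieg: float | None = None
    v_z_max: float | None = None
    K_z: float | None = None
    K_igz: float | None = None
    K_iez: float | None = None
    v_o_max: float | None = None
    K_o: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "v_g_max", "K_g", "K_ieg", "v_z_max", "K_z", "K_igz",
            "K_iez", "v_o_max", "K_o",
        ):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.v_g_max is not None and (self.K_g is None or self.K_ieg is None):
            raise ValueError("glucose uptake requires K_g and K_ieg")
        if self.v_z_max is not None and (
            self.K_z is None or self.K_igz is None or self.K_iez is None
        ):
            raise ValueError("xylose uptake requires K_z, K_igz and K_iez")
        if self.v_z_max is None and any(
            getattr(self, n) is not None for n in ("K_z", "K_igz", "K_iez")
        ):
            raise ValueError("xylose constants given but v_z_max is absent")
        if self.v_o_max is not None and self.K_o is None:
            raise ValueError("oxygen uptake requires K_o")

    def with_(self, **updates: float | None) -> "UptakeParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **updates)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# Published parameter sets for the two yeasts.  The respiratory-deficient
# S. cerevisiae strain has no xylose transport; its maximum glucose uptake
# differs between pure culture (21.5) and co-culture (18.5), a recalibration
# that accounts for the more efficient S. stipitis glucose uptake when the
# species compete.  The context is always selected explicitly by the caller.
CEREVISIAE_PURE = UptakeParams(
    v_g_max=21.5, K_g=0.5, K_ieg=10.0, v_o_max=2.5, K_o=0.005
)
CEREVISIAE_COCULTURE = CEREVISIAE_PURE.with_(v_g_max=18.5)
STIPITIS = UptakeParams(
    v_g_max=6.5, K_g=1.0, K_ieg=10.0,
    v_z_max=5.5, K_z=0.25, K_igz=0.5, K_iez=4.5,
    v_o_max=11.0, K_o=0.0125,
)


def table_params(species: str, context: str = "pure_culture") -> UptakeParams:
    """Default parameter set for ``species`` in a given culture context.

    Parameters
    ----------
    species:
        ``"cerevisiae"`` or ``"stipitis"`` (any label containing one of
        those substrings).
    context:
        ``"pure_culture"`` or ``"co_culture"``.  Only the S. cerevisiae
        maximum glucose uptake rate depends on the context.
    """
    if context not in ("pure_culture", "co_culture"):
        raise ValueError(f"unknown context {context!r}")
    key = species.lower()
    if "cerevisiae" in key:
        return CEREVISIAE_PURE if context == "pure_culture" else CEREVISIAE_COCULTURE
    if "stipitis" in key:
        return STIPITIS
    raise KeyError(f"no default parameters for species {species!r}")


def _check_nonnegative(**concentrations: float) -> None:
    for name, value in concentrations.items():
        if value < 0:
            raise ValueError(f"negative concentration {name}={value}")


def glucose_uptake_bound(G: float, E: float, p: UptakeParams) -> float:
    """Glucose uptake cap v_g,max * G/(K_g+G) * 1/(1+E/K_ieg), mmol/gdw/h."""
    _check_nonnegative(G=G, E=E)
    if p.v_g_max is None:
        return 0.0
    return p.v_g_max * G / (p.K_g + G) / (1.0 + E / p.K_ieg)


def xylose_uptake_bound(Z: float, G: float, E: float, p: UptakeParams) -> float:
    """Xylose uptake cap with glucose repression and ethanol inhibition.

    v_z,max * Z/(K_z+Z) * 1/(1+G/K_igz) * 1/(1+E/K_iez); zero for species
    without a xylose transport system.
    """
    _check_nonnegative(Z=Z, G=G, E=E)
    if p.v_z_max is None:
        return 0.0
    repression = 1.0 if math.isinf(p.K_igz) else 1.0 / (1.0 + G / p.K_igz)
    inhibition = 1.0 if math.isinf(p.K_iez) else 1.0 / (1.0 + E / p.K_iez)
    return p.v_z_max * Z / (p.K_z + Z) * repression * inhibition


def oxygen_uptake_bound(O: float, p: UptakeParams) -> float:
    """Oxygen uptake cap v_o,max * O/(K_o+O), mmol/gdw/h (O in mM)."""
    _check_nonnegative(O=O)
    if p.v_o_max is None:
        return 0.0
    return p.v_o_max * O / (p.K_o + O)


def uptake_caps(G: float, Z: float, E: float, O: float, p: UptakeParams) -> dict:
    """Evaluate all three caps at once; keys match the exchange map."""
    return {
        "glucose": glucose_uptake_bound(G, E, p),
        "xylose": xylose_uptake_bound(Z, G, E, p),
        "oxygen": oxygen_uptake_bound(O, p),
    }
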
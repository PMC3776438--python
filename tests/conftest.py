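"""Shared fixtures and the closed-form oracle for toy-network optima."""

from __future__ import annotations

import pytest

from dfba_coculture import (
    BatchConditions,
    CultureState,
    ToyNetworkConfig,
    make_toy_community,
    make_toy_species,
    table_params,
)


def toy_optimum(cfg: ToyNetworkConfig, caps: dict, resp_ko: bool = False):
    """Hand-computed FBA optimum of a toy network (no ethanol catabolism).

    Glucose is always worth consuming (fermentation yields ATP without
    oxygen), so the optimum consumes the full glucose cap and allocates
    the oxygen cap greedily across the oxygen-consuming routes ranked by
    ATP gained per O2: upgrading fermented glucose to respiration, and
    xylose catabolism.  Returns None when the maintenance demand cannot
    be met, else a dict with mu and the exchange-flux magnitudes.
    """
    assert "ethanol" not in cfg.substrates, "oracle assumes no ethanol uptake"
    u = caps.get("glucose", 0.0) if "glucose" in cfg.substrates else 0.0
    z = caps.get("xylose", 0.0) if "xylose" in cfg.substrates else 0.0
    o = caps.get("oxygen", 0.0)

    atp = cfg.atp_per_glucose_ferm * u
    routes = []
    if not resp_ko and "glucose" in cfg.substrates:
        gain = (cfg.atp_per_glucose_resp - cfg.atp_per_glucose_ferm)
        routes.append((gain / cfg.o2_per_glucose_resp, u * cfg.o2_per_glucose_resp, "glc"))
    if "xylose" in cfg.substrates:
        routes.append((cfg.atp_per_xylose / cfg.o2_per_xylose, z * cfg.o2_per_xylose, "xyl"))
    routes.sort(key=lambda r: -r[0])

    o_left, o2_used = o, {}
    for rate, o2_max, name in routes:
        take = min(o_left, o2_max)
        atp += rate * take
        o2_used[name] = take
        o_left -= take
    if atp < cfg.maintenance - 1e-12:
        return None
    ferm_glc = u - o2_used.get("glc", 0.0) / cfg.o2_per_glucose_resp
    xyl = o2_used.get("xyl", 0.0) / cfg.o2_per_xylose
    return {
        "mu": (atp - cfg.maintenance) / cfg.atp_per_biomass,
        "ethanol": cfg.ethanol_per_glucose * ferm_glc
        + cfg.ethanol_per_xylose * xyl,
        "oxygen": o - o_left,
        "glucose": u,
        "xylose": xyl,
    }


@pytest.fixture
def glucose_cfg():
    return ToyNetworkConfig(substrates=("glucose",))


@pytest.fixture
def diauxic_cfg():
    return ToyNetworkConfig(substrates=("glucose", "xylose"))


@pytest.fixture
def cerevisiae_model(glucose_cfg):
    """Respiration-competent glucose-only member (wild type)."""
    return make_toy_species(
        glucose_cfg, "cerevisiae", params=table_params("cerevisiae")
    )


@pytest.fixture
def stipitis_model(diauxic_cfg):
    return make_toy_species(diauxic_cfg, "stipitis")


@pytest.fixture
def toy_community():
    """Respiratory-deficient cerevisiae-like + diauxic stipitis-like pair."""
    return make_toy_community()


@pytest.fixture
def coculture_conditions():
    """The optimized batch design: 0.1/0.9 g/L inoculum, 16/8 g/L sugars."""
    return BatchConditions(
        kla=10.1,
        initial=CultureState(X_c=0.1, X_s=0.9, G=16.0, Z=8.0, E=0.0, O=0.24),
        t_end=40.0,
        context="co_culture",
    )
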
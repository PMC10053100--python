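"""Deterministic three-route exposure dose and health risk computation.

Average daily dose (ADD, mg/(kg*d)) per route:

    ingestion:  C * IngR * EFreq * ED / (BW * AT) * 1e-6
    dermal:     C * SA * AF * ABS * EFreq * ED / (BW * AT) * 1e-6
    inhalation: C * InhR * EFreq * ED / (PEF * BW * AT) * 1e-6

Noncancer doses average over AT_nc, cancer doses over AT_ca. Hazard
quotients HQ = ADD/RfD sum to the hazard index HI; cancer risks
CR = ADD*SF sum to the total cancer risk TCR. A metal-route enters HI/TCR
only if the corresponding RfD/SF is configured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .io_model import (
    ConfigError,
    ExposureParams,
    ROUTES,
    ToxicityTable,
)

__all__ = [
    "DoseResult",
    "RiskResult",
    "route_dose",
    "average_daily_dose",
    "compute_doses",
    "hazard_index",
    "cancer_risk",
    "deterministic_risk",
    "classify_tcr",
]

log = logging.getLogger(__name__)

Number = Union[float, np.ndarray]

_ROUTE_PARAMS = {
    "ingestion": ("IngR", "EFreq", "ED", "BW"),
    "dermal": ("SA", "AF", "ABS", "EFreq", "ED", "BW"),
    "inhalation": ("InhR", "EFreq", "ED", "PEF", "BW"),
}

#: conventional cancer-risk bands
TCR_NEGLIGIBLE = 1e-6
TCR_UNACCEPTABLE = 1e-4


def _require(p: Mapping[str, Number], names: tuple[str, ...], route: str) -> None:
    missing = [n for n in names if n not in p]
    if missing:
        raise ConfigError(f"missing exposure parameter(s) {missing} for route {route!r}")


def route_dose(C: Number, p: Mapping[str, Number], route: str, at_days: Number) -> Number:
    """Dose kernel shared by the deterministic and Monte Carlo paths.

    ``p`` maps exposure-factor names to scalars or aligned arrays; the
    expression is identical either way, which is what guarantees that a
    degenerate Monte Carlo run reproduces the deterministic result exactly.
    """
    if route == "ingestion":
        _require(p, _ROUTE_PARAMS[route], route)
        return C * p["IngR"] * p["EFreq"] * p["ED"] / (p["BW"] * at_days) * 1e-6
    if route == "dermal":
        _require(p, _ROUTE_PARAMS[route], route)
        return (C * p["SA"] * p["AF"] * p["ABS"] * p["EFreq"] * p["ED"]
                / (p["BW"] * at_days) * 1e-6)
    if route == "inhalation":
        _require(p, _ROUTE_PARAMS[route], route)
        return (C * p["InhR"] * p["EFreq"] * p["ED"]
                / (p["PEF"] * p["BW"] * at_days) * 1e-6)
    raise ConfigError(f"unknown route {route!r}")


def average_daily_dose(
    C: float,
    params: ExposureParams,
    population: str,
    route: str,
    averaging: str = "nc",
) -> float:
    """ADD at point-value exposure parameters for one route.

    ``averaging`` selects the averaging time: ``"nc"`` (noncancer, AT_nc)
    or ``"ca"`` (cancer, AT_ca).
    """
    if C < 0:
        raise ValueError("concentration must be >= 0")
    if averaging not in ("nc", "ca"):
        raise ValueError("averaging must be 'nc' or 'ca'")
    p = params.point_values(population)
    at_key = "AT_nc" if averaging == "nc" else "AT_ca"
    if at_key not in p:
        raise ConfigError(f"missing exposure parameter {at_key!r}")
    return float(route_dose(C, p, route, p[at_key]))


@dataclass
class DoseResult:
    """Per-metal, per-route doses for one population (both averaging times)."""

    population: str
    add_nc: pd.DataFrame   # metals x routes, averaged over AT_nc
    add_ca: pd.DataFrame   # metals x routes, averaged over AT_ca


def compute_doses(
    conc: Mapping[str, float], params: ExposureParams, population: str
) -> DoseResult:
    """Doses for every metal and route at point-value parameters."""
    p = params.point_values(population)
    for key in ("AT_nc", "AT_ca"):
        if key not in p:
            raise ConfigError(f"missing exposure parameter {key!r}")
    metals = list(conc)
    nc = pd.DataFrame(index=metals, columns=list(ROUTES), dtype=float)
    ca = pd.DataFrame(index=metals, columns=list(ROUTES), dtype=float)
    for metal in metals:
        for route in ROUTES:
            nc.loc[metal, route] = route_dose(conc[metal], p, route, p["AT_nc"])
            ca.loc[metal, route] = route_dose(conc[metal], p, route, p["AT_ca"])
    return DoseResult(population=population, add_nc=nc, add_ca=ca)


@dataclass
class RiskResult:
    """Hazard and cancer risk summaries for one population.

    ``hq``/``cr`` hold NaN where no RfD/SF is configured; HI and TCR are
    exact sums of the present entries.
    """

    population: str
    hq: pd.DataFrame
    hi_per_metal: pd.Series
    hi: float
    cr: pd.DataFrame
    tcr_per_metal: pd.Series
    tcr: float
    hi_exceeds: bool
    tcr_band: str


def classify_tcr(tcr: float) -> str:
    """Band a total cancer risk against the 1e-6 / 1e-4 convention."""
    if tcr == TCR_NEGLIGIBLE:
        return "at threshold"
    if tcr < TCR_NEGLIGIBLE:
        return "negligible"
    if tcr <= TCR_UNACCEPTABLE:
        return "acceptable"
    return "unacceptable"


def hazard_index(dose: DoseResult, tox: ToxicityTable) -> tuple[pd.DataFrame, pd.Series, float]:
    """HQ per metal-route (NaN where no RfD), per-metal sums, and HI."""
    metals = list(dose.add_nc.index)
    hq = pd.DataFrame(np.nan, index=metals, columns=list(ROUTES))
    for metal in metals:
        for route in ROUTES:
            rfd = tox.rfd_for(metal, route)
            if rfd is None:
                log.debug("no RfD for %s/%s; route skipped in HI", metal, route)
                continue
            hq.loc[metal, route] = dose.add_nc.loc[metal, route] / rfd
    per_metal = hq.sum(axis=1, skipna=True)
    return hq, per_metal, float(per_metal.sum())


def cancer_risk(dose: DoseResult, tox: ToxicityTable) -> tuple[pd.DataFrame, pd.Series, float]:
    """CR per metal-route (NaN where no SF), per-metal sums, and TCR."""
    metals = list(dose.add_ca.index)
    cr = pd.DataFrame(np.nan, index=metals, columns=list(ROUTES))
    for metal in metals:
        for route in ROUTES:
            sf = tox.sf_for(metal, route)
            if sf is None:
                continue
            cr.loc[metal, route] = dose.add_ca.loc[metal, route] * sf
    per_metal = cr.sum(axis=1, skipna=True)
    return cr, per_metal, float(per_metal.sum())


def deterministic_risk(
    conc: Mapping[str, float],
    params: ExposureParams,
    tox: ToxicityTable,
    population: str,
) -> RiskResult:
    """Full point-estimate risk assessment for one population."""
    if tox.is_empty:
        raise ConfigError("toxicity table is empty; cannot assess risk")
    dose = compute_doses(conc, params, population)
    hq, hi_pm, hi = hazard_index(dose, tox)
    cr, tcr_pm, tcr = cancer_risk(dose, tox)
    return RiskResult(
        population=population,
        hq=hq, hi_per_metal=hi_pm, hi=hi,
        cr=cr, tcr_per_metal=tcr_pm, tcr=tcr,
        hi_exceeds=hi > 1.0,
        tcr_band=classify_tcr(tcr),
    )
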
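"""Probabilistic (Monte Carlo) health risk assessment.

Concentrations and exposure factors are described by distribution specs,
sampled independently per iteration, and pushed through the same dose/risk
kernel as the deterministic path. Summaries report means, percentile bands
(linear interpolation between order statistics, the type-7 convention) and
threshold exceedance probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .hra import route_dose
from .io_model import (
    ConfigError,
    DistributionSpec,
    ExposureParams,
    MetalSummary,
    ROUTES,
    SampleTable,
    ToxicityTable,
    ValidationError,
)

__all__ = [
    "MCDraws",
    "RiskDistribution",
    "ContributionReport",
    "PERCENTILE_LEVELS",
    "sample_inputs",
    "run_mc",
    "contribution_report",
    "lognormal_specs_from_summary",
    "lognormal_specs_from_samples",
]

PERCENTILE_LEVELS: tuple[float, ...] = (5, 10, 25, 50, 75, 90, 95)


def lognormal_specs_from_summary(
    summary: Mapping[str, MetalSummary]
) -> dict[str, DistributionSpec]:
    """Lognormal concentration specs moment-matched to a summary table."""
    return {
        metal: DistributionSpec(family="lognormal", mean=s.mean, sd=s.sd)
        for metal, s in summary.items()
    }


def lognormal_specs_from_samples(samples: SampleTable) -> dict[str, DistributionSpec]:
    """Lognormal specs moment-matched to the sample table's mean/SD."""
    out = {}
    for metal in samples.metals:
        v = samples.conc[metal].to_numpy(float)
        out[metal] = DistributionSpec(
            family="lognormal", mean=float(v.mean()), sd=float(v.std(ddof=1))
        )
    return out


@dataclass
class MCDraws:
    """Per-population draw tables: exposure factors plus ``C_<metal>`` columns."""

    tables: dict[str, pd.DataFrame]
    n_iter: int
    seed: int
    metals: list[str]


def sample_inputs(
    conc_dists: Mapping[str, DistributionSpec],
    params: ExposureParams,
    n_iter: int,
    seed: int,
) -> MCDraws:
    """Draw all stochastic inputs for every population.

    Concentrations are drawn once per iteration and shared across
    populations (both populations face the same soil); exposure factors are
    drawn independently per population. Everything is reproducible from
    ``seed``.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    metals = list(conc_dists)
    conc_draws = {f"C_{m}": conc_dists[m].sample(rng, n_iter) for m in metals}
    tables = {}
    for pop in sorted(params.params):
        cols = dict(conc_draws)
        for name, spec in params.params[pop].items():
            cols[name] = spec.sample(rng, n_iter)
        tables[pop] = pd.DataFrame(cols)
    return MCDraws(tables=tables, n_iter=n_iter, seed=seed, metals=metals)


@dataclass
class RiskDistribution:
    """Monte Carlo HI / TCR draws with percentile and exceedance summaries."""

    population: str
    hi: np.ndarray
    tcr: np.ndarray
    hq_metal: pd.DataFrame    # n_iter x metals (routes summed)
    cr_metal: pd.DataFrame
    n_iter: int
    seed: int
    percentile_levels: tuple[float, ...] = PERCENTILE_LEVELS

    @property
    def mean_hi(self) -> float:
        return float(self.hi.mean())

    @property
    def mean_tcr(self) -> float:
        return float(self.tcr.mean())

    def percentiles(self, which: str = "hi") -> pd.Series:
        v = self.hi if which == "hi" else self.tcr
        return pd.Series(
            np.percentile(v, self.percentile_levels),
            index=[f"p{int(q)}" for q in self.percentile_levels],
        )

    def exceedance(self, which: str, threshold: float) -> float:
        """P(HI > t) or P(TCR > t) by direct counting."""
        v = self.hi if which == "hi" else self.tcr
        return float((v > threshold).mean())

    def summary_frame(self) -> pd.DataFrame:
        rows = {}
        for name, v in (("HI", self.hi), ("TCR", self.tcr)):
            row = {
                "mean": v.mean(),
                "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
            }
            row.update(self.percentiles("hi" if name == "HI" else "tcr").to_dict())
            rows[name] = row
        df = pd.DataFrame.from_dict(rows, orient="index")
        df["P_gt_1"] = [self.exceedance("hi", 1.0), np.nan]
        df["P_gt_1e-6"] = [np.nan, self.exceedance("tcr", 1e-6)]
        df["P_gt_1e-4"] = [np.nan, self.exceedance("tcr", 1e-4)]
        df["n_iter"] = self.n_iter
        df["seed"] = self.seed
        return df


def run_mc(draws: MCDraws, tox: ToxicityTable) -> dict[str, RiskDistribution]:
    """Propagate the draw tables through the dose/risk model.

    Applies the shared dose kernel per iteration (vectorized), divides by
    RfD / multiplies by SF exactly as the deterministic path does, and
    stores the full HI/TCR vectors.
    """
    if tox.is_empty:
        raise ConfigError("toxicity table is empty; cannot assess risk")
    out = {}
    for pop, table in draws.tables.items():
        p = {name: table[name].to_numpy() for name in table.columns
             if not name.startswith("C_")}
        for key in ("AT_nc", "AT_ca"):
            if key not in p:
                raise ConfigError(f"missing exposure parameter {key!r} for {pop!r}")
        n = draws.n_iter
        hq_m = pd.DataFrame(0.0, index=range(n), columns=draws.metals)
        cr_m = pd.DataFrame(0.0, index=range(n), columns=draws.metals)
        for metal in draws.metals:
            C = table[f"C_{metal}"].to_numpy()
            for route in ROUTES:
                rfd = tox.rfd_for(metal, route)
                if rfd is not None:
                    add = route_dose(C, p, route, p["AT_nc"])
                    hq_m[metal] += add / rfd
                sf = tox.sf_for(metal, route)
                if sf is not None:
                    add = route_dose(C, p, route, p["AT_ca"])
                    cr_m[metal] += add * sf
        out[pop] = RiskDistribution(
            population=pop,
            hi=hq_m.sum(axis=1).to_numpy(),
            tcr=cr_m.sum(axis=1).to_numpy(),
            hq_metal=hq_m,
            cr_metal=cr_m,
            n_iter=n,
            seed=draws.seed,
        )
    return out


@dataclass
class ContributionReport:
    """Each metal's percentage share of mean HI and mean TCR."""

    population: str
    hi_share_percent: pd.Series
    tcr_share_percent: pd.Series


def contribution_report(dist: RiskDistribution) -> ContributionReport:
    """Shares of mean HI / mean TCR attributable to each metal.

    share = mean(per-metal HQ or CR) / mean(HI or TCR) * 100. If the mean
    TCR is zero the shares are undefined and reported as NaN.
    """
    mean_hq = dist.hq_metal.mean(axis=0)
    mean_cr = dist.cr_metal.mean(axis=0)
    hi_tot, tcr_tot = mean_hq.sum(), mean_cr.sum()
    hi_share = 100.0 * mean_hq / hi_tot if hi_tot > 0 else mean_hq * np.nan
    tcr_share = 100.0 * mean_cr / tcr_tot if tcr_tot > 0 else mean_cr * np.nan
    return ContributionReport(
        population=dist.population,
        hi_share_percent=hi_share,
        tcr_share_percent=tcr_share,
    )
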
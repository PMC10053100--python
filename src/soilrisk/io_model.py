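"""Domain types, readers/writers and configuration handling.

The tabular input is a plain CSV with one row per sampling site: a site
label, planar coordinates and one concentration column (mg/kg) per analyte.
Configuration lives in a single YAML (or JSON) file with three blocks:
``reference`` (background, guide and MDL values), ``toxicity`` (per-metal,
per-route RfD and SF) and ``exposure`` (per-population exposure factors,
each either a point value or a distribution spec).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_METALS",
    "REFERENCE_ELEMENT",
    "ROUTES",
    "POPULATIONS",
    "SoilriskError",
    "SchemaError",
    "ValidationError",
    "ConfigError",
    "DistributionSpec",
    "SampleTable",
    "ReferenceValues",
    "ToxicityTable",
    "ExposureParams",
    "MetalSummary",
    "read_samples",
    "write_samples",
    "read_summary",
    "load_config",
    "load_default_config",
    "default_config_path",
    "default_summary_path",
]

DEFAULT_METALS: tuple[str, ...] = ("Cd", "Cr", "Cu", "Zn", "Ni", "Pb")
REFERENCE_ELEMENT = "Mn"
ROUTES: tuple[str, ...] = ("ingestion", "dermal", "inhalation")
POPULATIONS: tuple[str, ...] = ("adult", "child")

#: exposure factors understood by the dose model, per population
EXPOSURE_PARAM_NAMES: tuple[str, ...] = (
    "IngR", "InhR", "EFreq", "ED", "BW", "AT_nc", "AT_ca", "SA", "AF", "ABS", "PEF",
)

_SITE_ALIASES = ("site_id", "site", "id")
_X_ALIASES = ("x", "longitude", "lon")
_Y_ALIASES = ("y", "latitude", "lat")


class SoilriskError(Exception):
    """Base class for all package errors."""


class SchemaError(SoilriskError):
    """A required column or config key is missing."""


class ValidationError(SoilriskError):
    """Data present but invalid (negative, non-numeric, duplicated...)."""


class ConfigError(SoilriskError):
    """Inconsistent or incomplete configuration."""


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

_FAMILIES = ("point", "normal", "lognormal", "uniform", "triangular")


@dataclass(frozen=True)
class DistributionSpec:
    """A univariate distribution for a scalar model input.

    ``lognormal`` is parameterised by its *arithmetic* mean and SD; the
    underlying log-scale parameters are moment-matched internally
    (mu = ln(m^2 / sqrt(m^2 + s^2)), sigma^2 = ln(1 + s^2 / m^2)).

    Optional truncation bounds are honoured by rejection sampling and must
    keep the support non-negative.
    """

    family: str
    mean: Optional[float] = None
    sd: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    mode: Optional[float] = None
    trunc_low: Optional[float] = None
    trunc_high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.family == "point":
            if self.mean is None:
                raise ValidationError("point distribution requires a mean value")
        elif self.family in ("normal", "lognormal"):
            if self.mean is None or self.sd is None:
                raise ValidationError(f"{self.family} requires mean and sd")
            if self.sd < 0:
                raise ValidationError("sd must be >= 0")
            if self.family == "lognormal" and self.mean <= 0:
                raise ValidationError("lognormal arithmetic mean must be > 0")
        elif self.family == "uniform":
            if self.low is None or self.high is None:
                raise ValidationError("uniform requires low and high")
            if self.high < self.low:
                raise ValidationError("uniform requires low <= high")
        elif self.family == "triangular":
            if self.low is None or self.high is None or self.mode is None:
                raise ValidationError("triangular requires low, mode and high")
            if not (self.low <= self.mode <= self.high):
                raise ValidationError("triangular requires low <= mode <= high")
        if self.trunc_low is not None and self.trunc_low < 0:
            raise ValidationError("truncation must keep the support non-negative")
        if (
            self.trunc_low is not None
            and self.trunc_high is not None
            and self.trunc_high < self.trunc_low
        ):
            raise ValidationError("invalid truncation bounds")

    # -- sampling ----------------------------------------------------------

    def _draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "point":
            return np.full(n, float(self.mean))
        if self.family == "normal":
            return rng.normal(self.mean, self.sd, size=n)
        if self.family == "lognormal":
            if self.sd == 0:
                return np.full(n, float(self.mean))
            mu, sigma = lognormal_params(self.mean, self.sd)
            return rng.lognormal(mu, sigma, size=n)
        if self.family == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        return rng.triangular(self.low, self.mode, self.high, size=n)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` values, applying truncation by rejection."""
        lo, hi = self.trunc_low, self.trunc_high
        out = self._draw(rng, n)
        if lo is None and hi is None:
            return out
        lo_v = -np.inf if lo is None else lo
        hi_v = np.inf if hi is None else hi
        bad = (out < lo_v) | (out > hi_v)
        attempts = 0
        while bad.any():
            n_bad = int(bad.sum())
            out[bad] = self._draw(rng, n_bad)
            bad = (out < lo_v) | (out > hi_v)
            attempts += 1
            if attempts > 1000:
                raise ValidationError(
                    "truncation rejection acceptance below 0.1%; "
                    "check distribution parameters against bounds"
                )
        return out

    def mean_value(self) -> float:
        """Analytic mean of the untruncated distribution (point collapse)."""
        if self.family in ("point", "normal", "lognormal"):
            return float(self.mean)
        if self.family == "uniform":
            return (self.low + self.high) / 2.0
        return (self.low + self.mode + self.high) / 3.0

    @classmethod
    def from_config(cls, obj) -> "DistributionSpec":
        """Build from a config entry: a bare number or a mapping with ``dist``."""
        if isinstance(obj, (int, float)):
            return cls(family="point", mean=float(obj))
        if not isinstance(obj, Mapping):
            raise ValidationError(f"cannot interpret {obj!r} as a distribution")
        d = {k: v for k, v in obj.items()}
        family = str(d.pop("dist", d.pop("family", "point")))
        kw = {}
        for src, dst in (
            ("mean", "mean"), ("sd", "sd"), ("min", "low"), ("low", "low"),
            ("max", "high"), ("high", "high"), ("mode", "mode"),
            ("trunc_low", "trunc_low"), ("trunc_high", "trunc_high"),
        ):
            if src in d and d[src] is not None:
                kw[dst] = float(d[src])
        # for bounded families min/max are parameters; otherwise truncation
        if family in ("normal", "lognormal", "point"):
            if "low" in kw:
                kw["trunc_low"] = kw.pop("low")
            if "high" in kw:
                kw["trunc_high"] = kw.pop("high")
        return cls(family=family, **kw)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) matching an arithmetic mean and SD."""
    if mean <= 0:
        raise ValidationError("lognormal mean must be > 0")
    var = sd * sd
    mu = math.log(mean * mean / math.sqrt(mean * mean + var))
    sigma = math.sqrt(math.log(1.0 + var / (mean * mean)))
    return mu, sigma


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """Per-site analyte concentrations (mg/kg) with planar coordinates."""

    site_id: list[str]
    x: np.ndarray
    y: np.ndarray
    conc: pd.DataFrame  # index = site_id, one column per analyte

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.validate()

    @property
    def metals(self) -> list[str]:
        return list(self.conc.columns)

    @property
    def n_sites(self) -> int:
        return len(self.site_id)

    def validate(self) -> None:
        if len(set(self.site_id)) != len(self.site_id):
            dup = sorted({s for s in self.site_id if self.site_id.count(s) > 1})
            raise ValidationError(f"duplicate site_id: {dup}")
        if not (len(self.site_id) == len(self.x) == len(self.y) == len(self.conc)):
            raise ValidationError("site_id, coordinates and concentrations disagree in length")
        vals = self.conc.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = self.conc.index[~np.isfinite(vals).all(axis=1)][0]
            raise ValidationError(f"non-finite concentration at site {bad!r}")
        if (vals < 0).any():
            bad = self.conc.index[(vals < 0).any(axis=1)][0]
            raise ValidationError(f"negative concentration at site {bad!r}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"site_id": self.site_id, "x": self.x, "y": self.y})
        return pd.concat([df, self.conc.reset_index(drop=True)], axis=1)

    def subset_metals(self, metals: Sequence[str]) -> pd.DataFrame:
        missing = [m for m in metals if m not in self.conc.columns]
        if missing:
            raise SchemaError(f"metals not in sample table: {missing}")
        return self.conc.loc[:, list(metals)]


def read_samples(path, schema: Optional[Sequence[str]] = None) -> SampleTable:
    """Read a delimited sample file and validate it against ``schema``.

    ``schema`` lists the analyte columns that must be present (defaults to
    the six metals plus the reference element). Values below the detection
    limit are kept as reported; substitution is a downstream choice.
    """
    if schema is None:
        schema = list(DEFAULT_METALS) + [REFERENCE_ELEMENT]
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}

    def pick(aliases: Iterable[str], what: str) -> str:
        for a in aliases:
            if a in cols:
                return cols[a]
        raise SchemaError(f"missing {what} column (one of {tuple(aliases)})")

    site_col = pick(_SITE_ALIASES, "site id")
    x_col = pick(_X_ALIASES, "x coordinate")
    y_col = pick(_Y_ALIASES, "y coordinate")
    missing = [m for m in schema if m not in df.columns]
    if missing:
        raise SchemaError(f"missing concentration column(s): {missing}")

    site_id = [str(s) for s in df[site_col]]
    conc = df.loc[:, list(schema)].copy()
    for col in conc.columns:
        try:
            conc[col] = pd.to_numeric(conc[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[site_col][pd.to_numeric(conc[col], errors="coerce").isna()].iloc[0]
            raise ValidationError(
                f"non-numeric concentration for {col!r} at site {bad!r}"
            ) from None
    conc.index = pd.Index(site_id, name="site_id")
    return SampleTable(site_id=site_id, x=df[x_col].to_numpy(float),
                       y=df[y_col].to_numpy(float), conc=conc)


def write_samples(table: SampleTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# summary stats input (matched-sample generation target)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetalSummary:
    """Target marginal moments and range for one analyte."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.max < self.min:
            raise ValidationError("summary max < min")
        if self.mean <= 0 or self.sd < 0:
            raise ValidationError("summary requires mean > 0 and sd >= 0")


def read_summary(path) -> dict[str, MetalSummary]:
    """Read a YAML mapping metal -> {mean, sd, min, max}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise SchemaError("summary file must map metal -> {mean, sd, min, max}")
    out = {}
    for metal, row in raw.items():
        try:
            out[str(metal)] = MetalSummary(
                mean=float(row["mean"]), sd=float(row["sd"]),
                min=float(row["min"]), max=float(row["max"]),
            )
        except KeyError as e:
            raise SchemaError(f"summary for {metal}: missing key {e}") from None
    return out


# ---------------------------------------------------------------------------
# configuration blocks
# ---------------------------------------------------------------------------


@dataclass
class ReferenceValues:
    """Background, guide and detection-limit values (all mg/kg)."""

    background: dict[str, float]
    guide: dict[str, float]
    mdl: dict[str, float]
    mn_background: float

    def __post_init__(self) -> None:
        for name, d in (("background", self.background), ("guide", self.guide),
                        ("mdl", self.mdl)):
            for metal, v in d.items():
                if not (v > 0):
                    raise ValidationError(f"{name}[{metal}] must be > 0, got {v}")
        if not (self.mn_background > 0):
            raise ValidationError("mn_background must be > 0")

    def require_metals(self, metals: Sequence[str], what: str = "background") -> None:
        table = getattr(self, what)
        missing = [m for m in metals if m not in table]
        if missing:
            raise ConfigError(f"no {what} value configured for: {missing}")


@dataclass
class ToxicityTable:
    """Per-metal, per-route reference doses and slope factors.

    Missing entries are allowed and explicit: a metal contributes to HI only
    through routes with an RfD and to TCR only through routes with an SF.
    """

    rfd: dict[str, dict[str, float]] = field(default_factory=dict)
    sf: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table in (("rfd", self.rfd), ("sf", self.sf)):
            for metal, routes in table.items():
                for route, v in routes.items():
                    if route not in ROUTES:
                        raise ValidationError(f"unknown route {route!r} in {name}[{metal}]")
                    if not (v > 0):
                        raise ValidationError(f"{name}[{metal}][{route}] must be > 0")

    @property
    def is_empty(self) -> bool:
        return not self.rfd and not self.sf

    def metals(self) -> list[str]:
        return sorted(set(self.rfd) | set(self.sf))

    def rfd_for(self, metal: str, route: str) -> Optional[float]:
        return self.rfd.get(metal, {}).get(route)

    def sf_for(self, metal: str, route: str) -> Optional[float]:
        return self.sf.get(metal, {}).get(route)


@dataclass
class ExposureParams:
    """Per-population exposure factors, each a :class:`DistributionSpec`."""

    params: dict[str, dict[str, DistributionSpec]]

    def __post_init__(self) -> None:
        if set(self.params) != set(POPULATIONS):
            raise ValidationError(
                f"population set must be exactly {set(POPULATIONS)}, got {set(self.params)}"
            )
        for pop, entries in self.params.items():
            for name, spec in entries.items():
                if spec.family == "point" and not (spec.mean > 0):
                    raise ValidationError(f"exposure {pop}.{name} must be > 0")
            at_nc = entries.get("AT_nc")
            at_ca = entries.get("AT_ca")
            if at_nc is not None and at_ca is not None:
                if at_ca.mean_value() < at_nc.mean_value():
                    raise ValidationError(f"{pop}: AT_ca must be >= AT_nc")

    def spec(self, population: str, name: str) -> DistributionSpec:
        try:
            return self.params[population][name]
        except KeyError:
            raise ConfigError(
                f"missing exposure parameter {name!r} for population {population!r}"
            ) from None

    def point_values(self, population: str) -> dict[str, float]:
        """Collapse every spec to its analytic mean (deterministic use)."""
        if population not in self.params:
            raise ConfigError(f"unknown population {population!r}")
        return {k: v.mean_value() for k, v in self.params[population].items()}


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------


def _float_map(obj, where: str) -> dict[str, float]:
    if obj is None:
        return {}
    if not isinstance(obj, Mapping):
        raise SchemaError(f"config block {where!r} must be a mapping")
    return {str(k): float(v) for k, v in obj.items()}


def load_config(path) -> tuple[ReferenceValues, ToxicityTable, Optional[ExposureParams]]:
    """Load the ``reference``, ``toxicity`` and ``exposure`` blocks.

    ``reference`` is mandatory. ``toxicity`` and ``exposure`` may be absent,
    in which case an empty table / ``None`` is returned and downstream risk
    stages will refuse to run.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise SchemaError("config file must be a mapping with a 'reference' block")
    if "reference" not in raw:
        raise SchemaError("config is missing the 'reference' block")

    ref_raw = raw["reference"]
    if "mn_background" not in ref_raw:
        raise ConfigError("reference block must set mn_background (no default is shipped)")
    ref = ReferenceValues(
        background=_float_map(ref_raw.get("background"), "reference.background"),
        guide=_float_map(ref_raw.get("guide"), "reference.guide"),
        mdl=_float_map(ref_raw.get("mdl"), "reference.mdl"),
        mn_background=float(ref_raw["mn_background"]),
    )

    tox_raw = raw.get("toxicity") or {}
    tox = ToxicityTable(
        rfd={m: _float_map(r, f"toxicity.rfd.{m}") for m, r in (tox_raw.get("rfd") or {}).items()},
        sf={m: _float_map(r, f"toxicity.sf.{m}") for m, r in (tox_raw.get("sf") or {}).items()},
    )
    for metal in tox.metals():
        if metal not in ref.background:
            raise ConfigError(
                f"metal {metal!r} present in toxicity but absent from reference block"
            )

    expo_raw = raw.get("exposure")
    expo = None
    if expo_raw is not None:
        expo = ExposureParams(params={
            str(pop): {str(k): DistributionSpec.from_config(v) for k, v in entries.items()}
            for pop, entries in expo_raw.items()
        })
    return ref, tox, expo


def default_config_path() -> str:
    """Path to the shipped default configuration (EPA-conventional stand-ins)."""
    return str(resources.files("soilrisk").joinpath("data/default_config.yaml"))


def default_summary_path() -> str:
    """Path to the shipped demo survey summary statistics."""
    return str(resources.files("soilrisk").joinpath("data/demo_summary.yaml"))


def load_default_config() -> tuple[ReferenceValues, ToxicityTable, Optional[ExposureParams]]:
    return load_config(default_config_path())
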
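"""Pollution screening indices: summary statistics, enrichment factors,
Sutherland-style classification and Pearson correlation analysis."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import (
    ConfigError,
    REFERENCE_ELEMENT,
    ReferenceValues,
    SampleTable,
    ValidationError,
)

__all__ = [
    "EF_CLASS_LABELS",
    "DEFAULT_EF_BOUNDS",
    "EnrichmentResult",
    "summarize",
    "cv_percent",
    "enrichment_factor",
    "classify_ef",
    "ef_class_rank",
    "correlation_matrix",
]

log = logging.getLogger(__name__)

#: left-closed class bounds and ordinal labels for enrichment factors
DEFAULT_EF_BOUNDS: tuple[float, ...] = (2.0, 5.0, 20.0, 40.0)
EF_CLASS_LABELS: tuple[str, ...] = (
    "deficient-to-minimal",
    "moderate",
    "significant",
    "very high",
    "extreme",
)


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100 * sd / mean."""
    if mean == 0:
        return float("nan") if sd else 0.0
    return 100.0 * sd / mean


def summarize(samples: SampleTable, ref: ReferenceValues,
              metals: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-metal min/max/mean/SD, CV% and exceedance rates.

    SD uses the n-1 (sample) denominator. Exceedance is the percentage of
    sites whose concentration is strictly above the background / guide
    value.
    """
    if samples.n_sites < 2:
        raise ValidationError("summary statistics require at least 2 sites (sd undefined)")
    if metals is None:
        metals = [m for m in samples.metals if m in ref.background]
    ref.require_metals(metals, "background")
    ref.require_metals(metals, "guide")
    conc = samples.subset_metals(metals)
    n = len(conc)
    rows = {}
    for metal in metals:
        v = conc[metal].to_numpy(float)
        mean = v.mean()
        sd = v.std(ddof=1)
        rows[metal] = {
            "min": v.min(),
            "max": v.max(),
            "mean": mean,
            "sd": sd,
            "cv_percent": cv_percent(mean, sd),
            "er_background_percent": 100.0 * (v > ref.background[metal]).sum() / n,
            "er_guide_percent": 100.0 * (v > ref.guide[metal]).sum() / n,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(metals)]


# ---------------------------------------------------------------------------
# enrichment factors
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    """Per-site, per-metal enrichment factors and ordinal classes."""

    ef: pd.DataFrame            # sites x metals, unitless
    ef_class: pd.DataFrame      # sites x metals, ordinal labels
    excluded_sites: list[str] = field(default_factory=list)


def classify_ef(ef_value: float,
                bounds: Sequence[float] = DEFAULT_EF_BOUNDS,
                labels: Sequence[str] = EF_CLASS_LABELS) -> str:
    """Map an enrichment factor onto an ordinal class (left-closed bins)."""
    if not (ef_value > 0):
        raise ValidationError(f"enrichment factor must be > 0, got {ef_value}")
    if len(labels) != len(bounds) + 1:
        raise ConfigError("need exactly one more label than bound")
    idx = int(np.searchsorted(np.asarray(bounds, float), ef_value, side="right"))
    return labels[idx]


def ef_class_rank(label: str, labels: Sequence[str] = EF_CLASS_LABELS) -> int:
    """Ordinal rank of a class label (0 = lowest)."""
    return list(labels).index(label)


def enrichment_factor(
    samples: SampleTable,
    ref: ReferenceValues,
    metals: Optional[Sequence[str]] = None,
    reference_element: str = REFERENCE_ELEMENT,
    bounds: Sequence[float] = DEFAULT_EF_BOUNDS,
    labels: Sequence[str] = EF_CLASS_LABELS,
) -> EnrichmentResult:
    """Double-ratio enrichment factor against the reference element.

    EF = (C_i / C_ref)_sample / (C_i / C_ref)_background, with the site's
    own reference-element concentration in the denominator. Sites with a
    zero or missing reference-element value are excluded with a warning.
    """
    if reference_element not in samples.conc.columns:
        raise ConfigError(f"reference element {reference_element!r} not in sample table")
    if metals is None:
        metals = [m for m in samples.metals
                  if m != reference_element and m in ref.background]
    ref.require_metals(metals, "background")

    ref_conc = samples.conc[reference_element].to_numpy(float)
    ok = ref_conc > 0
    excluded = [s for s, good in zip(samples.site_id, ok) if not good]
    if excluded:
        warnings.warn(
            f"{len(excluded)} site(s) excluded from enrichment factors "
            f"(non-positive {reference_element}): {excluded}",
            stacklevel=2,
        )

    conc = samples.subset_metals(metals).to_numpy(float)
    bg = np.array([ref.background[m] for m in metals])
    with np.errstate(divide="ignore", invalid="ignore"):
        ef_vals = (conc / ref_conc[:, None]) / (bg / ref.mn_background)[None, :]
    ef_vals[~ok, :] = np.nan

    idx = pd.Index(samples.site_id, name="site_id")
    ef = pd.DataFrame(ef_vals, index=idx, columns=list(metals))
    classes = ef.map(
        lambda v: classify_ef(v, bounds, labels) if np.isfinite(v) and v > 0 else ""
    )
    return EnrichmentResult(ef=ef, ef_class=classes, excluded_sites=excluded)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def correlation_matrix(
    samples: SampleTable, metals: Optional[Sequence[str]] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix with two-sided p-values.

    Returns ``(r, p)`` DataFrames. Constant columns yield NaN entries and a
    warning rather than a silent zero.
    """
    if samples.n_sites < 3:
        raise ValidationError("correlation requires at least 3 sites")
    if metals is None:
        metals = samples.metals
    conc = samples.subset_metals(metals)
    m = len(metals)
    r = np.eye(m)
    p = np.zeros((m, m))
    const = [c for c in metals if conc[c].nunique() <= 1]
    if const:
        warnings.warn(f"constant column(s), correlation undefined: {const}", stacklevel=2)
    for i in range(m):
        for j in range(i + 1, m):
            if metals[i] in const or metals[j] in const:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(conc[metals[i]], conc[metals[j]])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(list(metals))
    return (pd.DataFrame(r, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx))
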
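"""Uncertainty-weighted positive matrix factorization receptor model.

Decomposes a site x analyte concentration matrix X into nonnegative source
contributions G (n x k, mg/kg) and source profiles F (k x m) by minimizing

    Q = sum_ij ((x_ij - (G F)_ij) / u_ij)^2

where u_ij are per-cell measurement uncertainties. The solver is an
iteratively reweighted multiplicative-update scheme (weights 1/u^2) with
multiple seeded random restarts; the lowest-Q converged run is reported.

Cell uncertainties follow the standard detection-limit construction:
u = sqrt((error_fraction * c)^2 + MDL^2) when c > MDL, and u = 5/6 * MDL
otherwise. A robust variant downweights cells whose scaled residual
exceeds a threshold, giving the Q_robust diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io_model import ConfigError, ReferenceValues, SampleTable, ValidationError

__all__ = [
    "PMFSolution",
    "SourceReport",
    "build_uncertainty",
    "fit_pmf",
    "scan_factors",
    "source_report",
    "robust_downweight",
    "match_factors",
]

log = logging.getLogger(__name__)

_EPS = 1e-300          # denominator guard in multiplicative updates
_CONV_WINDOW = 20      # consecutive small-change iterations for convergence

ArrayLike = Union[np.ndarray, pd.DataFrame]


def build_uncertainty(
    samples: SampleTable,
    ref: ReferenceValues,
    error_fraction: float = 0.1,
    metals: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-cell uncertainties from the error fraction and MDLs.

    Branches on the concentration against the metal's MDL:
    ``c > MDL  -> sqrt((error_fraction*c)^2 + MDL^2)``;
    ``c <= MDL -> 5/6 * MDL``.
    """
    if not (0.0 < error_fraction < 1.0):
        raise ValidationError("error_fraction must be in (0, 1)")
    if metals is None:
        metals = samples.metals
    missing = [m for m in metals if m not in ref.mdl]
    if missing:
        raise ConfigError(f"no MDL configured for: {missing}")
    conc = samples.subset_metals(metals).to_numpy(float)
    mdl = np.array([ref.mdl[m] for m in metals])
    above = conc > mdl[None, :]
    u = np.where(
        above,
        np.sqrt((error_fraction * conc) ** 2 + mdl[None, :] ** 2),
        5.0 / 6.0 * mdl[None, :],
    )
    return pd.DataFrame(u, index=samples.conc.index, columns=list(metals))


# ---------------------------------------------------------------------------
# solution containers
# ---------------------------------------------------------------------------


@dataclass
class PMFSolution:
    """Best-run factorization with diagnostics.

    Profiles are normalized so each row of F sums to 1 and G carries the
    mass; the product G.F (and hence Q and all percentage reports) is
    invariant to this convention.
    """

    G: np.ndarray
    F: np.ndarray
    Q_true: float
    Q_robust: float
    residuals: np.ndarray
    converged: bool
    run_seed: int
    r2: np.ndarray                      # per-analyte fit r^2 (obs vs recon)
    metals: list[str] = field(default_factory=list)
    site_id: list[str] = field(default_factory=list)
    n_iter: int = 0
    q_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def k(self) -> int:
        return self.G.shape[1]

    @property
    def reconstruction(self) -> np.ndarray:
        return self.G @ self.F


@dataclass
class SourceReport:
    """Percentage attribution of mass to factors."""

    factor_total_percent: pd.Series      # per factor, sums to 100
    metal_factor_percent: pd.DataFrame   # factors x metals, columns sum to 100


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


def _as_array(a: ArrayLike) -> np.ndarray:
    return a.to_numpy(float) if isinstance(a, pd.DataFrame) else np.asarray(a, float)


def _single_run(
    X: np.ndarray,
    W: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, bool, int, np.ndarray]:
    """One multiplicative-update run from a random nonnegative start."""
    n, m = X.shape
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    G = np.abs(rng.normal(size=(n, k))) * scale
    F = np.abs(rng.normal(size=(k, m))) * scale

    WX = W * X
    q_hist = np.empty(max_iter + 1)
    q_prev = float(np.sum(W * (X - G @ F) ** 2))
    q_hist[0] = q_prev
    small = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        GF = G @ F
        G *= (WX @ F.T) / np.maximum((W * GF) @ F.T, _EPS)
        GF = G @ F
        F *= (G.T @ WX) / np.maximum(G.T @ (W * GF), _EPS)
        q = float(np.sum(W * (X - G @ F) ** 2))
        q_hist[it] = q
        rel = abs(q_prev - q) / max(q_prev, _EPS)
        small = small + 1 if rel < tol else 0
        q_prev = q
        if small >= _CONV_WINDOW or q <= 1e-17 * max(q_hist[0], 1.0):
            # second clause: an (almost) exact factorization was found; the
            # relative-change rule cannot trigger while Q decays geometrically
            converged = True
            break
    return G, F, converged, it, q_hist[: it + 1]


def fit_pmf(
    X: ArrayLike,
    U: ArrayLike,
    k: int,
    n_runs: int = 20,
    seed: int = 0,
    max_iter: int = 3000,
    tol: float = 1e-9,
    robust_threshold: float = 4.0,
    metals: Optional[Sequence[str]] = None,
    site_id: Optional[Sequence[str]] = None,
) -> PMFSolution:
    """Fit the weighted factorization, keeping the best of ``n_runs`` starts.

    Convergence of a run means the relative change of the objective stayed
    below ``tol`` for 20 consecutive iterations. If no run converges the
    lowest-Q solution is still returned with ``converged=False`` and a
    warning.
    """
    if metals is None and isinstance(X, pd.DataFrame):
        metals = list(X.columns)
    if site_id is None and isinstance(X, pd.DataFrame):
        site_id = [str(s) for s in X.index]
    Xa, Ua = _as_array(X), _as_array(U)
    if Xa.shape != Ua.shape:
        raise ValidationError("X and U must have the same shape")
    n, m = Xa.shape
    if k < 1 or k >= min(n, m):
        raise ValidationError(f"k={k} out of range for a {n}x{m} matrix")
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    if (Ua <= 0).any():
        raise ValidationError("uncertainties must be strictly positive")

    W = 1.0 / (Ua * Ua)
    best = None
    child_seeds = np.random.SeedSequence(seed).spawn(n_runs)
    for run, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        G, F, conv, n_it, q_hist = _single_run(Xa, W, k, rng, max_iter, tol)
        q = q_hist[-1]
        key = (not conv, q)  # prefer converged runs, then lowest Q
        if best is None or key < best[0]:
            best = (key, G, F, conv, run, n_it, q_hist)
    _, G, F, conv, run, n_it, q_hist = best
    if not conv:
        warnings.warn(
            f"PMF did not converge in any of {n_runs} runs (k={k}); "
            "returning the lowest-Q solution",
            stacklevel=2,
        )

    # normalize: F rows sum to 1, G carries the concentration scale
    row = F.sum(axis=1)
    nz = row > 0
    F[nz] /= row[nz, None]
    G[:, nz] *= row[nz][None, :]

    resid = Xa - G @ F
    q_true = float(np.sum((resid / Ua) ** 2))
    u_rob = _inflate_uncertainty(resid, Ua, robust_threshold)
    q_robust = float(np.sum((resid / u_rob) ** 2))

    recon = G @ F
    r2 = np.empty(m)
    for j in range(m):
        sx, sy = Xa[:, j].std(), recon[:, j].std()
        if sx == 0 or sy == 0:
            r2[j] = np.nan
        else:
            r2[j] = np.corrcoef(Xa[:, j], recon[:, j])[0, 1] ** 2

    return PMFSolution(
        G=G, F=F, Q_true=q_true, Q_robust=q_robust, residuals=resid,
        converged=conv, run_seed=run, r2=r2,
        metals=list(metals) if metals is not None else [],
        site_id=list(site_id) if site_id is not None else [],
        n_iter=n_it, q_history=q_hist,
    )


def _inflate_uncertainty(resid: np.ndarray, U: np.ndarray, threshold: float) -> np.ndarray:
    scaled = np.abs(resid / U)
    out = U.copy()
    mask = scaled > threshold
    out[mask] *= np.sqrt(scaled[mask] / threshold)
    return out


def robust_downweight(
    X: ArrayLike, U: ArrayLike, sol: PMFSolution, threshold: float = 4.0
) -> pd.DataFrame:
    """Inflate uncertainties of outlier cells (|scaled residual| > threshold).

    Each flagged cell's u is multiplied by sqrt(|e/u| / threshold), the
    conventional robust-mode downweighting; unflagged cells are unchanged.
    """
    if not (threshold > 0):
        raise ValidationError("threshold must be > 0")
    Xa, Ua = _as_array(X), _as_array(U)
    out = _inflate_uncertainty(Xa - sol.reconstruction, Ua, threshold)
    if isinstance(U, pd.DataFrame):
        return pd.DataFrame(out, index=U.index, columns=U.columns)
    return pd.DataFrame(out)


def scan_factors(
    X: ArrayLike,
    U: ArrayLike,
    k_range: Sequence[int],
    n_runs: int = 20,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit one model per candidate factor number and tabulate Q diagnostics.

    Returns a table of (k, Q_true, Q_robust, q_ratio, converged). Q should
    be non-increasing in k on the best runs; a violation is logged as an
    optimizer failure rather than hidden.
    """
    rows = []
    prev_q = np.inf
    for k in k_range:
        sol = fit_pmf(X, U, k=k, n_runs=n_runs, seed=seed, **fit_kwargs)
        if sol.Q_true > prev_q * (1 + 1e-9):
            log.warning(
                "Q increased from k=%s (%.4g) to k=%s (%.4g): optimizer failure",
                k - 1, prev_q, k, sol.Q_true,
            )
        prev_q = sol.Q_true
        rows.append({
            "k": k,
            "Q_true": sol.Q_true,
            "Q_robust": sol.Q_robust,
            "q_ratio": sol.Q_robust / sol.Q_true if sol.Q_true > 0 else np.nan,
            "converged": sol.converged,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def source_report(sol: PMFSolution) -> SourceReport:
    """Percentage attribution of reconstructed mass to each factor.

    Per metal: share of that metal's reconstructed mass contributed by each
    factor (columns sum to 100). Overall: each factor's share of the total
    reconstructed mass.
    """
    if not sol.converged:
        warnings.warn("reporting from a non-converged solution", stacklevel=2)
    # contributed mass of factor k to metal j: (sum_i g_ik) * f_kj
    mass = sol.G.sum(axis=0)[:, None] * sol.F        # k x m
    col_tot = mass.sum(axis=0)
    zero_factors = np.where(mass.sum(axis=1) == 0)[0]
    if zero_factors.size:
        warnings.warn(f"factor(s) {zero_factors.tolist()} contribute zero mass",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_metal = np.where(col_tot > 0, 100.0 * mass / col_tot, 0.0)
    total = mass.sum()
    overall = 100.0 * mass.sum(axis=1) / total if total > 0 else np.zeros(sol.k)

    factors = [f"F{i + 1}" for i in range(sol.k)]
    metals = sol.metals if sol.metals else [f"m{j + 1}" for j in range(sol.F.shape[1])]
    return SourceReport(
        factor_total_percent=pd.Series(overall, index=factors, name="percent"),
        metal_factor_percent=pd.DataFrame(per_metal, index=factors, columns=metals),
    )


def match_factors(F_est: np.ndarray, F_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal factor permutation by cosine similarity (Hungarian assignment).

    Returns ``(perm, sims)``: ``perm[i]`` is the estimated factor matched to
    true factor ``i`` and ``sims[i]`` the cosine similarity of that pair.
    Factor order in a factorization is arbitrary, so recovery checks must
    permute first.
    """
    from scipy.optimize import linear_sum_assignment

    def unit_rows(A):
        norm = np.linalg.norm(A, axis=1, keepdims=True)
        return A / np.maximum(norm, _EPS)

    sim = unit_rows(F_true) @ unit_rows(F_est).T
    rows, cols = linear_sum_assignment(-sim)
    return cols, sim[rows, cols]
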
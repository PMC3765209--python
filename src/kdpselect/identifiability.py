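"""Sensitivity, Fisher-information identifiability and correlation analysis.

Local practical identifiability is assessed through the Fisher information
matrix FIM = Σ (1/σᵢ²) (∂yᵢ/∂p)ᵀ(∂yᵢ/∂p): full rank means the active
parameters are locally identifiable, and the inverse FIM, rescaled to unit
diagonal, gives the parameter correlation matrix.  Parameter importance is
ranked by the msqr index, the sum of squared relative sensitivities
S = (pθ/y)·∂y/∂pθ over every measurement.  A pseudo-global variant repeats
the local analysis over a Sobol' low-discrepancy sample of parameter space
and averages with maximum-likelihood weights, so that parameter sets
unlikely to fit the data contribute little.

Derivatives are central finite differences with a relative step on the
parameters — simple and checkable by step halving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .kdp_model import (
    IntegratorSettings,
    KineticParameters,
    StructureVector,
)
from .objective import Dataset, ModelObjective, log_likelihood

__all__ = [
    "SensitivityMatrix",
    "FIMatrix",
    "CorrelationReport",
    "NonIdentifiableError",
    "relative_sensitivities",
    "msqr_indices",
    "fisher_information",
    "correlation_from_fim",
    "pseudo_global_analysis",
]

#: Predictions below this magnitude are treated as zero when normalising.
Y_FLOOR = 1e-12


class NonIdentifiableError(RuntimeError):
    """The FIM is rank deficient: correlation analysis is not applicable."""


@dataclass
class SensitivityMatrix:
    """Relative sensitivities S = (pθ/y)·∂y/∂pθ, one row per measurement.

    ``raw`` holds the un-normalised derivatives ∂y/∂pθ from the same finite
    differences, used to assemble the FIM.
    """

    values: np.ndarray  # (n_measurements, n_parameters)
    raw: np.ndarray
    parameters: tuple[str, ...]
    row_index: pd.DataFrame  # experiment_id, variable, time_h
    n_zero_floored: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.row_index.reset_index(drop=True),
             pd.DataFrame(self.values, columns=list(self.parameters))],
            axis=1,
        )


@dataclass
class FIMatrix:
    values: np.ndarray
    parameters: tuple[str, ...]

    def scaled(self) -> np.ndarray:
        """Unit-diagonal rescaling D·FIM·D, D = diag(FIM)^(-1/2).

        Parameters span many orders of magnitude, so the raw-unit FIM is
        ill-conditioned by construction; the diagonal scaling preserves the
        mathematical rank and leaves the derived correlation matrix
        unchanged, while making the numerical rank decision meaningful.
        Zero-diagonal (totally insensitive) parameters are left unscaled.
        """
        d = np.sqrt(np.diag(self.values))
        d = np.where(d > 0.0, d, 1.0)
        return self.values / np.outer(d, d)

    def rank(self, rtol: float = 1e-12) -> tuple[int, float]:
        """Numerical rank of the scaled FIM and the singular-value cutoff used."""
        sv = np.linalg.svd(self.scaled(), compute_uv=False)
        cutoff = rtol * (sv[0] if sv.size else 0.0)
        return int(np.sum(sv > cutoff)), float(cutoff)

    @property
    def full_rank(self) -> bool:
        return self.rank()[0] == len(self.parameters)


@dataclass
class CorrelationReport:
    parameters: tuple[str, ...]
    correlation: np.ndarray
    fim_rank: int
    rank_cutoff: float
    identifiable: bool
    msqr: pd.Series
    ranking: tuple[str, ...]
    weights: np.ndarray | None = None
    n_failed_points: int = 0

    def correlation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.correlation, index=list(self.parameters),
                            columns=list(self.parameters))


def _row_index(dataset: Dataset) -> pd.DataFrame:
    rows = []
    for e in dataset.experiments:
        t = e.table[["variable", "time_h"]].copy()
        t.insert(0, "experiment_id", e.design.label)
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


def relative_sensitivities(
    s: StructureVector,
    p: KineticParameters,
    dataset: Dataset,
    rel_step: float = 1e-4,
    settings: IntegratorSettings = IntegratorSettings(),
    parameters: tuple[str, ...] | None = None,
) -> SensitivityMatrix:
    """Central finite-difference relative sensitivities of all measured values.

    Differentiates with respect to the active continuous parameters of the
    structure (a multiplicative step, equivalently a step on log p).
    Entries at measurements with |y| below :data:`Y_FLOOR` are set to zero
    and counted.  If a perturbed simulation fails, the step is halved once
    before giving up.
    """
    params = parameters or s.active_reals()
    mo = ModelObjective(dataset, settings)
    y0 = mo.predict(s, p)
    if y0 is None:
        raise RuntimeError("baseline simulation failed in sensitivity analysis")
    raw = np.empty((y0.size, len(params)))
    for j, name in enumerate(params):
        theta = getattr(p, name)
        h = rel_step
        for attempt in range(2):
            hi = mo.predict(s, p.replace(**{name: theta * (1.0 + h)}))
            lo = mo.predict(s, p.replace(**{name: theta * (1.0 - h)}))
            if hi is not None and lo is not None:
                break
            h *= 0.5
        else:  # pragma: no cover - defensive
            hi = lo = None
        if hi is None or lo is None:
            raise RuntimeError(
                f"perturbed simulation failed for parameter {name} (step {h:g})"
            )
        raw[:, j] = (hi - lo) / (2.0 * h * theta)
    mask = np.abs(y0) >= Y_FLOOR
    values = np.zeros_like(raw)
    theta_vec = np.array([getattr(p, n) for n in params])
    values[mask] = raw[mask] * (theta_vec / y0[mask, None])
    return SensitivityMatrix(
        values=values, raw=raw, parameters=tuple(params),
        row_index=_row_index(dataset), n_zero_floored=int(np.sum(~mask)),
    )


def msqr_indices(sm: SensitivityMatrix, convention: str = "sum") -> pd.Series:
    """Per-parameter msqr ranking index.

    ``sum`` (default): plain sum of squared relative sensitivities over all
    experiments/variables/measurements.  ``rms``: the root-mean-square
    variant.  Either way, ranking is by descending index.
    """
    sq = np.sum(sm.values**2, axis=0)
    if convention == "rms":
        sq = np.sqrt(sq / sm.values.shape[0])
    elif convention != "sum":
        raise ValueError(f"unknown msqr convention {convention!r}")
    return pd.Series(sq, index=list(sm.parameters))


def fisher_information(
    sm: SensitivityMatrix | np.ndarray,
    dataset: Dataset | None = None,
    sigmas: np.ndarray | None = None,
    parameters: tuple[str, ...] | None = None,
) -> FIMatrix:
    """FIM = Σᵢ (1/σᵢ²)·(∂yᵢ/∂p)ᵀ(∂yᵢ/∂p); symmetric positive semi-definite."""
    if isinstance(sm, SensitivityMatrix):
        raw = sm.raw
        parameters = parameters or sm.parameters
    else:
        raw = np.asarray(sm, dtype=float)
        parameters = parameters or tuple(f"p{i}" for i in range(raw.shape[1]))
    if sigmas is None:
        if dataset is None:
            raise ValueError("either a dataset or sigmas must be given")
        sigmas = dataset.sigmas
    if np.any(sigmas <= 0):
        raise ValueError("all sigmas must be > 0")
    W = raw / sigmas[:, None]
    fim = W.T @ W
    return FIMatrix(values=0.5 * (fim + fim.T), parameters=tuple(parameters))


def correlation_from_fim(fim: FIMatrix, rtol: float = 1e-12) -> np.ndarray:
    """Correlation matrix from the inverse FIM, rescaled to unit diagonal.

    Raises :class:`NonIdentifiableError` for a rank-deficient FIM — the
    inverse-FIM covariance only exists when the parameters are identifiable.
    """
    rank, cutoff = fim.rank(rtol)
    k = len(fim.parameters)
    if rank < k:
        raise NonIdentifiableError(
            f"FIM rank {rank} < {k} (singular values below {cutoff:.3e} treated as zero)"
        )
    # correlations are invariant under diagonal rescaling of the FIM, so
    # invert the well-conditioned scaled matrix
    V = np.linalg.inv(fim.scaled())
    d = np.sqrt(np.diag(V))
    C = V / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def _report_from_local(
    sm: SensitivityMatrix, fim: FIMatrix, rtol: float = 1e-12,
    msqr_convention: str = "sum",
) -> CorrelationReport:
    rank, cutoff = fim.rank(rtol)
    identifiable = rank == len(fim.parameters)
    corr = correlation_from_fim(fim, rtol) if identifiable else np.full(
        (len(fim.parameters),) * 2, np.nan
    )
    msqr = msqr_indices(sm, msqr_convention)
    ranking = tuple(msqr.sort_values(ascending=False).index)
    return CorrelationReport(
        parameters=fim.parameters, correlation=corr, fim_rank=rank,
        rank_cutoff=cutoff, identifiable=identifiable, msqr=msqr, ranking=ranking,
    )


def local_analysis(
    s: StructureVector,
    p: KineticParameters,
    dataset: Dataset,
    rel_step: float = 1e-4,
    settings: IntegratorSettings = IntegratorSettings(),
    msqr_convention: str = "sum",
    parameters: tuple[str, ...] | None = None,
) -> CorrelationReport:
    """Sensitivities, FIM rank and correlation matrix at a single point.

    By default analyses every active continuous parameter of ``s``;
    ``parameters`` restricts the analysis to a subset (useful when nearly
    insensitive parameters would dominate the rank decision).
    """
    sm = relative_sensitivities(s, p, dataset, rel_step, settings, parameters=parameters)
    fim = fisher_information(sm, dataset)
    return _report_from_local(sm, fim, msqr_convention=msqr_convention)


def sobol_sample(
    bounds: np.ndarray, n_points: int, seed: int
) -> np.ndarray:
    """Sobol' low-discrepancy points in the given (log-space) box."""
    bounds = np.asarray(bounds, dtype=float)
    sampler = qmc.Sobol(d=bounds.shape[0], scramble=True, rng=np.random.default_rng(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # n need not be a power of two
        u = sampler.random(n_points)
    return qmc.scale(u, bounds[:, 0], bounds[:, 1])


def pseudo_global_analysis(
    s: StructureVector,
    reference: KineticParameters,
    bounds: np.ndarray,
    dataset: Dataset,
    n_points: int = 2**10,
    seed: int = 0,
    rel_step: float = 1e-4,
    settings: IntegratorSettings = IntegratorSettings(),
    weighting: str = "likelihood",
    msqr_convention: str = "sum",
) -> CorrelationReport:
    """Likelihood-weighted average of local analyses over a Sobol' sample.

    ``bounds`` is an (n_active, 2) array of log10 bounds over the active
    continuous parameters of ``s`` (same space the optimizer searches).  At
    each Sobol' point the local sensitivities, msqr indices and — where the
    FIM is invertible — the correlation matrix are computed; the report
    averages them with weights proportional to each point's likelihood
    (log-shifted before exponentiation for overflow control).  Points whose
    simulation fails, or whose FIM is rank deficient, receive zero weight
    and are counted.  ``weighting="uniform"`` gives the unweighted mean.
    """
    if weighting not in ("likelihood", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    params = s.active_reals()
    bounds = np.asarray(bounds, dtype=float)
    if bounds.shape != (len(params), 2):
        raise ValueError(f"bounds must have shape ({len(params)}, 2)")
    X = sobol_sample(bounds, n_points, seed)
    mo = ModelObjective(dataset, settings)

    logLs, corrs, msqrs = [], [], []
    n_failed = 0
    for x in X:
        p = reference.replace(**dict(zip(params, (10.0**x).tolist())))
        try:
            pred = mo.predict(s, p)
            if pred is None or not np.all(np.isfinite(pred)):
                raise RuntimeError("simulation failure")
            sm = relative_sensitivities(s, p, dataset, rel_step, settings, parameters=params)
            fim = fisher_information(sm, dataset)
            corr = correlation_from_fim(fim)
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        logLs.append(log_likelihood(dataset, pred))
        corrs.append(corr)
        msqrs.append(msqr_indices(sm, msqr_convention).to_numpy())
    if not corrs:
        raise NonIdentifiableError("no Sobol' point produced an invertible FIM")

    logLs = np.asarray(logLs)
    if weighting == "likelihood":
        w = np.exp(logLs - logLs.max())
    else:
        w = np.ones_like(logLs)
    w = w / w.sum()
    corr_avg = np.tensordot(w, np.asarray(corrs), axes=1)
    msqr_avg = pd.Series(np.tensordot(w, np.asarray(msqrs), axes=1), index=list(params))
    ranking = tuple(msqr_avg.sort_values(ascending=False).index)
    return CorrelationReport(
        parameters=tuple(params), correlation=np.clip(corr_avg, -1.0, 1.0),
        fim_rank=len(params), rank_cutoff=0.0, identifiable=True,
        msqr=msqr_avg, ranking=ranking, weights=w, n_failed_points=n_failed,
    )
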
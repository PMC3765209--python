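"""Maximum-likelihood objective, AIC and residual summaries.

The model-selection cost is the Akaike information criterion
AIC = -2*Jml + 2*Np, where Jml is the Gaussian log-likelihood of the
time-course data under known heteroscedastic standard deviations and Np is
the number of estimated decision variables active in the candidate
structure.  :class:`CaseStudyProblem` packages dataset + superstructure into
a single callable over the mixed decision vector, the form consumed by
:mod:`kdpselect.minlp_search`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .kdp_model import (
    DECISION_REALS,
    ExperimentDesign,
    IntegratorSettings,
    KineticParameters,
    StructureVector,
    initial_state,
    simulate,
    STATE_NAMES,
    SteadyStateError,
    AlgebraicSolveError,
)

__all__ = [
    "Experiment",
    "Dataset",
    "ObjectiveValue",
    "ResidualSummary",
    "log_likelihood",
    "count_active_parameters",
    "aic",
    "residual_summary",
    "ModelObjective",
    "CaseStudyProblem",
    "objective_evaluate",
    "PENALTY_BASE",
    "FEASIBLE_CAP",
]

#: Base value encoding an infeasible (failed-simulation) evaluation.
PENALTY_BASE = 1e10
#: Feasible objective values are capped below this in the search ordering so
#: that every feasible point compares strictly better than every penalty.
FEASIBLE_CAP = 1e9

_CSV_COLUMNS = ["experiment_id", "strain", "K_mM", "variable", "time_h", "value", "sigma"]


@dataclass
class Experiment:
    """One experiment: its design plus the measured table (variable, time_h, value, sigma)."""

    design: ExperimentDesign
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"variable", "time_h", "value", "sigma"} - set(self.table.columns)
        if missing:
            raise ValueError(f"measurement table missing columns {sorted(missing)}")
        if not (self.table["sigma"] > 0).all():
            raise ValueError("every measurement standard deviation must be > 0")
        bad = set(self.table["variable"]) - set(self.design.observed)
        if bad:
            raise ValueError(f"measured variables {sorted(bad)} not in design.observed")
        grid = np.asarray(self.design.t_grid)
        idx = np.searchsorted(grid, self.table["time_h"].to_numpy())
        idx = np.clip(idx, 0, grid.size - 1)
        lower = np.clip(idx - 1, 0, grid.size - 1)
        use_lower = np.abs(grid[lower] - self.table["time_h"]) < np.abs(
            grid[idx] - self.table["time_h"]
        )
        idx = np.where(use_lower, lower, idx)
        if not np.allclose(grid[idx], self.table["time_h"], rtol=0, atol=1e-9):
            raise ValueError("measurement times must lie on the design time grid")
        self._time_idx = idx.astype(np.intp)
        self._state_idx = np.array(
            [STATE_NAMES.index(v) for v in self.table["variable"]], dtype=np.intp
        )


class Dataset:
    """Measurements ỹ with standard deviations σ, organised by experiment.

    Flat views (values, sigmas) follow the concatenated row order of the
    per-experiment tables; model predictions must be aligned to that order.
    """

    def __init__(self, experiments: Sequence[Experiment]):
        if not experiments:
            raise ValueError("dataset must contain at least one experiment")
        self.experiments = list(experiments)
        self.values = np.concatenate([e.table["value"].to_numpy(float) for e in self.experiments])
        self.sigmas = np.concatenate([e.table["sigma"].to_numpy(float) for e in self.experiments])
        self.sigma_log_term = float(-0.5 * np.sum(np.log(2.0 * np.pi * self.sigmas**2)))

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    @property
    def n_measurements(self) -> int:
        return self.values.size

    def counts(self) -> dict:
        """NE, per-experiment NV and per-(experiment, variable) NM."""
        NV = {}
        NM = {}
        for i, e in enumerate(self.experiments):
            by_var = e.table.groupby("variable").size()
            NV[i] = int(by_var.size)
            for var, n in by_var.items():
                NM[(i, var)] = int(n)
        return {"NE": self.n_experiments, "NV": NV, "NM": NM}

    def predictions_from(self, trajectories: Sequence) -> np.ndarray | None:
        """Assemble the aligned prediction vector from one trajectory per experiment."""
        if len(trajectories) != self.n_experiments:
            raise ValueError("one trajectory per experiment required")
        parts = []
        for e, tr in zip(self.experiments, trajectories):
            if tr is None or not tr.ok:
                return None
            parts.append(tr.states[e._state_idx, e._time_idx])
        return np.concatenate(parts)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, e in enumerate(self.experiments):
            t = e.table.copy()
            t.insert(0, "experiment_id", e.design.label)
            t.insert(1, "strain", e.design.strain)
            t.insert(2, "K_mM", e.design.Kplus)
            rows.append(t[_CSV_COLUMNS])
        return pd.concat(rows, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        missing = set(_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset frame missing columns {sorted(missing)}")
        experiments = []
        for eid, sub in df.groupby("experiment_id", sort=False):
            strain = sub["strain"].iloc[0]
            Kplus = float(sub["K_mM"].iloc[0])
            grid = tuple(sorted(set(sub["time_h"].astype(float))))
            design = ExperimentDesign(
                strain=strain, Kplus=Kplus, t_grid=grid,
                observed=tuple(dict.fromkeys(sub["variable"])),
            )
            experiments.append(Experiment(design, sub[["variable", "time_h", "value", "sigma"]].reset_index(drop=True)))
        return cls(experiments)

    @classmethod
    def read_csv(cls, path) -> "Dataset":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class ObjectiveValue:
    """Likelihood, parameter count and AIC of one evaluated decision vector."""

    Jml: float
    Np: int
    aic: float
    feasible: bool = True
    penalty_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "Jml": self.Jml, "Np": self.Np, "aic": self.aic,
            "feasible": self.feasible, "penalty_reason": self.penalty_reason,
        }


@dataclass
class ResidualSummary:
    mean_percent: float
    n_used: int
    n_excluded: int = 0


def log_likelihood(dataset: Dataset, predictions: np.ndarray) -> float:
    """Gaussian log-likelihood of the data given aligned model predictions.

    Jml = Σ ln(1/√(2πσ²)) − ½ Σ ((ỹ−y)/σ)², summed over every measurement of
    every variable of every experiment; additive over experiments.
    """
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != dataset.values.shape:
        raise ValueError(
            f"predictions shape {predictions.shape} does not match "
            f"{dataset.values.shape} measurements"
        )
    resid = (dataset.values - predictions) / dataset.sigmas
    return dataset.sigma_log_term - 0.5 * float(resid @ resid)


def count_active_parameters(s: StructureVector, include_integers: bool = True) -> int:
    """Number of estimated decision variables Np for structure ``s``.

    Counts the active continuous parameters, and (by default) the active
    integer exponents plus the three structure binaries, since all are
    decision variables of the MINLP.  ``include_integers=False`` counts the
    continuous parameters only.
    """
    n = len(s.active_reals())
    if include_integers:
        n += len(s.active_exponents()) + 3
    return n


def aic(Jml: float, Np: int) -> float:
    """Akaike information criterion −2·Jml + 2·Np (smaller is better)."""
    if not math.isfinite(Jml):
        raise ValueError("Jml must be finite")
    if Np < 0 or Np != int(Np):
        raise ValueError("Np must be a non-negative integer")
    return -2.0 * Jml + 2.0 * Np


def residual_summary(dataset: Dataset, predictions: np.ndarray) -> ResidualSummary:
    """Mean relative residual |ỹ−y| / |ỹ| in percent, zero measurements excluded."""
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != dataset.values.shape:
        raise ValueError("predictions misaligned with dataset")
    nonzero = dataset.values != 0.0
    n_excluded = int(np.sum(~nonzero))
    rel = np.abs(dataset.values[nonzero] - predictions[nonzero]) / np.abs(dataset.values[nonzero])
    return ResidualSummary(
        mean_percent=float(100.0 * rel.mean()), n_used=int(nonzero.sum()),
        n_excluded=n_excluded,
    )


class ModelObjective:
    """Evaluates a (structure, parameters) pair of the superstructure against data.

    Simulation failures never raise: they are encoded as infeasible
    :class:`ObjectiveValue` records carrying a large finite penalty so that a
    metaheuristic sees a totally ordered objective.
    """

    def __init__(
        self,
        dataset: Dataset,
        settings: IntegratorSettings = IntegratorSettings(),
        count_integers: bool = True,
    ):
        self.dataset = dataset
        self.settings = settings
        self.count_integers = count_integers

    def predict(self, s: StructureVector, p: KineticParameters) -> np.ndarray | None:
        """Aligned predictions for every measurement, or None on failure."""
        y0_cache: dict[str, np.ndarray] = {}
        trajectories = []
        for e in self.dataset.experiments:
            strain = e.design.strain
            if strain not in y0_cache:
                try:
                    y0_cache[strain] = initial_state(s, p, strain, self.settings)
                except (SteadyStateError, AlgebraicSolveError):
                    return None
            tr = simulate(s, p, e.design, self.settings, y0=y0_cache[strain])
            if not tr.ok:
                return None
            trajectories.append(tr)
        return self.dataset.predictions_from(trajectories)

    def evaluate(self, s: StructureVector, p: KineticParameters) -> ObjectiveValue:
        Np = count_active_parameters(s, self.count_integers)
        pred = self.predict(s, p)
        if pred is None or not np.all(np.isfinite(pred)):
            return ObjectiveValue(
                Jml=float("nan"), Np=Np, aic=PENALTY_BASE + 1.0, feasible=False,
                penalty_reason="simulation failure",
            )
        Jml = log_likelihood(self.dataset, pred)
        if not math.isfinite(Jml):
            return ObjectiveValue(
                Jml=float("nan"), Np=Np, aic=PENALTY_BASE + 2.0, feasible=False,
                penalty_reason="non-finite likelihood",
            )
        return ObjectiveValue(Jml=Jml, Np=Np, aic=aic(Jml, Np))


class CaseStudyProblem:
    """The case-study MINLP over the mixed decision vector (p, q).

    Continuous decisions are searched in log10 space inside bounds
    nominal ×/÷ ``bounds_factor`` (the Khy bounds are fixed separately, its
    nominal value being undefined); integer decisions are the three binaries
    and five exponents.  ``__call__`` returns the scalar search objective:
    the AIC for feasible points (capped at :data:`FEASIBLE_CAP`) and a
    penalty ≥ :data:`PENALTY_BASE` for failed simulations, so every feasible
    point orders strictly better than every infeasible one.
    """

    def __init__(
        self,
        dataset: Dataset,
        reference: KineticParameters,
        bounds_factor: float = 100.0,
        Khy_bounds: tuple[float, float] = (1e-2, 1e2),
        settings: IntegratorSettings = IntegratorSettings(),
        count_integers: bool = True,
        exponent_max: int = 3,
    ):
        self.reference = reference
        self.model_objective = ModelObjective(dataset, settings, count_integers)
        lo = np.log10(reference.reals() / bounds_factor)
        hi = np.log10(reference.reals() * bounds_factor)
        k = DECISION_REALS.index("Khy")
        lo[k], hi[k] = np.log10(Khy_bounds[0]), np.log10(Khy_bounds[1])
        self.real_bounds = np.column_stack([lo, hi])
        self.int_bounds = np.array([[0, 1]] * 3 + [[0, exponent_max]] * 5)
        self.real_names = DECISION_REALS

    def decode(self, xr: np.ndarray, xi: np.ndarray) -> tuple[StructureVector, KineticParameters]:
        s = StructureVector.from_array(xi).canonical()
        p = self.reference.with_reals(10.0 ** np.asarray(xr, dtype=float))
        return s, p

    def encode(self, s: StructureVector, p: KineticParameters) -> tuple[np.ndarray, np.ndarray]:
        return np.log10(p.reals()), s.as_array()

    def evaluate(self, xr: np.ndarray, xi: np.ndarray) -> ObjectiveValue:
        s, p = self.decode(xr, xi)
        return self.model_objective.evaluate(s, p)

    def __call__(self, xr: np.ndarray, xi: np.ndarray) -> float:
        v = self.evaluate(xr, xi)
        return min(v.aic, FEASIBLE_CAP) if v.feasible else v.aic

    def residuals(self, xr: np.ndarray, xi: np.ndarray) -> np.ndarray | None:
        """Weighted residuals (ỹ−y)/σ for least-squares refinement of the reals."""
        s, p = self.decode(xr, xi)
        pred = self.model_objective.predict(s, p)
        if pred is None or not np.all(np.isfinite(pred)):
            return None
        return (self.model_objective.dataset.values - pred) / self.model_objective.dataset.sigmas

    def integer_neighbors(self, xi: np.ndarray) -> list[np.ndarray]:
        """Model-aware neighbourhood of a structure vector.

        Unit moves on every integer coordinate, plus compound moves for the
        binaries: switching a feedback loop on is proposed jointly with every
        admissible value of the exponents it activates (a loop whose Hill
        exponents are left at stale values would otherwise never look
        attractive), and switching it off zeroes them.
        """
        xi = np.asarray(xi, dtype=np.int64)
        lo, hi = self.int_bounds[:, 0], self.int_bounds[:, 1]
        out: list[np.ndarray] = []

        def push(z):
            z = np.clip(z, lo, hi)
            if not np.array_equal(z, xi) and not any(np.array_equal(z, o) for o in out):
                out.append(z)

        for i in range(xi.size):
            for delta in (-1, 1):
                z = xi.copy()
                z[i] += delta
                if lo[i] <= z[i] <= hi[i]:
                    push(z)
        # binaries: (bin1, n1), (bin2, (n2, n3)), (bin3, n5) at positions
        # (0, [3]), (1, [4, 5]), (2, [7]) of the decision vector
        for b, exps in ((0, (3,)), (1, (4, 5)), (2, (7,))):
            if xi[b] == 0:
                if len(exps) == 1:
                    for v in range(lo[exps[0]], hi[exps[0]] + 1):
                        z = xi.copy()
                        z[b] = 1
                        z[exps[0]] = v
                        push(z)
                else:
                    for v1 in range(lo[exps[0]], hi[exps[0]] + 1):
                        for v2 in range(lo[exps[1]], hi[exps[1]] + 1):
                            z = xi.copy()
                            z[b] = 1
                            z[exps[0]], z[exps[1]] = v1, v2
                            push(z)
            else:
                z = xi.copy()
                z[b] = 0
                for e in exps:
                    z[e] = 0
                push(z)
        return out


def objective_evaluate(
    s: StructureVector,
    p: KineticParameters,
    dataset: Dataset,
    settings: IntegratorSettings = IntegratorSettings(),
    count_integers: bool = True,
) -> ObjectiveValue:
    """Convenience one-shot evaluation of a decision vector against a dataset."""
    return ModelObjective(dataset, settings, count_integers).evaluate(s, p)
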
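"""The case-study recovery protocol: search, polish, summarise.

One place defines how the selection/estimation MINLP is actually run on a
dataset: several independent scatter-search runs over a cheaper
loose-tolerance objective (integration rtol 1e-6 / atol 1e-10 — ample for
ranking candidates), followed by one deep local polish of the overall best
point against the tight default objective.  The command-line `fit`, the
test suite and the acceptance script all call this entry point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kdp_model import IntegratorSettings, KineticParameters, StructureVector
from .minlp_search import RunResult, SearchSettings, local_refine, scatter_search
from .objective import CaseStudyProblem, Dataset, ObjectiveValue, residual_summary
from .synthetic_data import nominal_parameters

__all__ = ["StudyResult", "run_recovery_study", "SEARCH_SETTINGS_LOOSE"]

#: Integrator settings used during the global search phase.
SEARCH_SETTINGS_LOOSE = IntegratorSettings(rtol=1e-6, atol=1e-10)


@dataclass
class StudyResult:
    """Outcome of one full selection/estimation study on a dataset."""

    runs: list[RunResult]
    structure: StructureVector
    parameters: KineticParameters
    objective: ObjectiveValue
    best_value: float
    mean_residual_percent: float
    seed: int
    problem: CaseStudyProblem = field(repr=False)

    def run_structures(self) -> list[StructureVector]:
        return [StructureVector.from_array(r.best.integers).canonical() for r in self.runs]

    def deviations_percent(self, reference: KineticParameters) -> dict[str, float]:
        """Percent deviation of each active parameter from a reference set
        (parameters without a defined reference value are skipped)."""
        out = {}
        for name in self.structure.active_reals():
            if name == "Khy":
                continue
            ref = getattr(reference, name)
            out[name] = abs(getattr(self.parameters, name) - ref) / ref * 100.0
        return out


def run_recovery_study(
    dataset: Dataset,
    seed: int,
    n_runs: int = 3,
    budget: int = 9000,
    local_budget: int = 1000,
    polish_budget: int = 1200,
    n_diverse: int = 100,
    reference: KineticParameters | None = None,
    search_settings: IntegratorSettings = SEARCH_SETTINGS_LOOSE,
    final_settings: IntegratorSettings = IntegratorSettings(),
) -> StudyResult:
    """Solve the MINLP on ``dataset`` with ``n_runs`` independent searches.

    Run k uses seed ``seed + 1000·(k+1)``; all stochastic stages derive from
    ``seed``.  The returned best point is the overall winner after a deep
    polish on the tight objective.
    """
    if reference is None:
        reference = nominal_parameters()[1]
    loose = CaseStudyProblem(dataset, reference, settings=search_settings)
    tight = CaseStudyProblem(dataset, reference, settings=final_settings)

    runs = []
    for k in range(n_runs):
        settings = SearchSettings(
            seed=seed + 1000 * (k + 1), max_evaluations=budget,
            local_budget=local_budget, n_diverse=n_diverse,
        )
        runs.append(scatter_search(loose, loose.real_bounds, loose.int_bounds, settings))

    best = min(runs, key=lambda r: r.best_value)
    refined, _ = local_refine(
        tight, best.best, tight.real_bounds, tight.int_bounds, budget=polish_budget,
    )
    obj = tight.evaluate(refined.reals, refined.integers)
    s_fit, p_fit = tight.decode(refined.reals, refined.integers)
    pred = tight.model_objective.predict(s_fit, p_fit)
    resid = residual_summary(dataset, pred) if pred is not None else None
    return StudyResult(
        runs=runs, structure=s_fit, parameters=p_fit, objective=obj,
        best_value=obj.aic if obj.feasible else float("inf"),
        mean_residual_percent=resid.mean_percent if resid else float("nan"),
        seed=seed, problem=tight,
    )
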
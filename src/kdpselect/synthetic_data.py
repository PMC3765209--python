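"""In-silico dataset generation for the KdpD/KdpE case study.

The study conditions: two strains (wild type and a K⁺-uptake-defective
mutant) are each observed after a downshift to five extracellular K⁺ levels
(1, 10, 50, 100 and 500 mM); only the kdpFABC transcript and the KdpFABC
transporter complex are measurable, with 5% heteroscedastic (multiplicative
Gaussian) error.  Trajectories are simulated from the nominal parameter set
under the nominal structure — translation and proteolysis regulation active
(bin1 = bin2 = 1, n1 = 3, n2 = 1, n3 = 2), linear stimulus counteraction
with kinetic order three (bin3 = 0, n4 = 3).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kdp_model import (
    ExperimentDesign,
    IntegratorSettings,
    KineticParameters,
    StructureVector,
    initial_state,
    simulate,
)
from .objective import Dataset, Experiment

__all__ = [
    "GenerationProtocol",
    "nominal_parameters",
    "generate",
    "make_fixture_suite",
    "NOMINAL_STRUCTURE",
    "K_LEVELS_MM",
    "DEFAULT_T_GRID",
]

NOMINAL_STRUCTURE = StructureVector(bin1=1, bin2=1, bin3=0, n1=3, n2=1, n3=2, n4=3, n5=0)
K_LEVELS_MM = (1.0, 10.0, 50.0, 100.0, 500.0)
#: 15 equispaced observation times on the first hour after the K⁺ downshift.
DEFAULT_T_GRID = tuple(np.linspace(0.0, 1.0, 15))

_NOMINAL_REALS = {
    "k2": 5.18e7,
    "k3": 9.76e1,
    "alpha": 5.79e-2,
    "ktr": 1.00e3,
    "ktl": 4.96e3,
    "ktl2": 1.03e3,
    "ktl3": 2.05e3,
    "kz": 4.99e1,
    "kd2": 1.00e1,
    "DNA0": 6.16e-4,
    "Ka": 1.82e-7,
    "K": 1.00e3,
    "kd": 1.18e0,
    "khy": 2.00e6,
    "ktrans": 9.74e-1,
    "kdeg": 1.36e-1,
}


def nominal_parameters() -> tuple[StructureVector, KineticParameters]:
    """The nominal structure and parameter set used to generate the data.

    Khy carries no nominal value (it is inactive in the nominal structure,
    bin3 = 0) and is left at the class default.
    """
    return NOMINAL_STRUCTURE, KineticParameters(**_NOMINAL_REALS)


@dataclass
class GenerationProtocol:
    """Everything needed to (re)generate one in-silico dataset."""

    seed: int
    structure: StructureVector = NOMINAL_STRUCTURE
    parameters: KineticParameters = field(default_factory=lambda: nominal_parameters()[1])
    strains: tuple[str, ...] = ("wild", "mutant")
    K_levels: tuple[float, ...] = K_LEVELS_MM
    observed: tuple[str, ...] = ("mRNA", "KdpFABC")
    t_grid: tuple[float, ...] = DEFAULT_T_GRID
    noise_level: float = 0.05
    settings: IntegratorSettings = field(default_factory=IntegratorSettings)

    def __post_init__(self) -> None:
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if not (self.strains and self.K_levels and self.observed):
            raise ValueError("at least one strain, K level and observed variable required")

    def describe(self) -> dict:
        return {
            "seed": self.seed,
            "structure": dataclasses.asdict(self.structure),
            "parameters": dataclasses.asdict(self.parameters),
            "strains": list(self.strains),
            "K_levels_mM": list(self.K_levels),
            "observed": list(self.observed),
            "t_grid_h": list(self.t_grid),
            "noise_level": self.noise_level,
        }


def _sigma_floor(y: np.ndarray, noise_level: float) -> np.ndarray:
    # strictly positive sigmas even where a trajectory crosses zero
    floor = 1e-12 + noise_level * np.median(np.abs(y)) * 1e-6
    return np.maximum(noise_level * np.abs(y), floor)


def generate(protocol: GenerationProtocol) -> Dataset:
    """Simulate every strain × K⁺ level and perturb the observed values.

    Each observation is drawn as ỹ = y·(1 + ε·noise_level), ε ~ N(0, 1),
    and stored with σ = noise_level·|y| (floored away from zero).  Negative
    draws are kept as drawn.  Deterministic given ``protocol.seed``.
    """
    rng = np.random.default_rng(protocol.seed)
    s, p = protocol.structure, protocol.parameters
    experiments = []
    for strain in protocol.strains:
        y0 = initial_state(s, p, strain, protocol.settings)
        for Kplus in protocol.K_levels:
            design = ExperimentDesign(strain, Kplus, protocol.t_grid, protocol.observed)
            tr = simulate(s, p, design, protocol.settings, y0=y0)
            if not tr.ok:
                raise RuntimeError(
                    f"generation simulation failed for {design.label}: {tr.message}"
                )
            rows = []
            for var in protocol.observed:
                y = tr.get(var)
                sigma = _sigma_floor(y, max(protocol.noise_level, 1e-12))
                if protocol.noise_level > 0:
                    value = y * (1.0 + protocol.noise_level * rng.standard_normal(y.size))
                else:
                    value = y.copy()
                rows.append(pd.DataFrame({
                    "variable": var,
                    "time_h": np.asarray(design.t_grid),
                    "value": value,
                    "sigma": sigma,
                }))
            experiments.append(Experiment(design, pd.concat(rows, ignore_index=True)))
    return Dataset(experiments)


def make_fixture_suite(seed: int, outdir) -> dict[str, Path]:
    """Write the deterministic fixture datasets used by the test suite.

    Produces three CSV files: ``tiny`` (one wild-strain experiment, five
    time points), ``full`` (the complete 2 × 5 protocol) and ``noisefree``
    (the full protocol with zero noise).  A provenance JSON records each
    protocol and the seed.  Same seed → byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    protocols = {
        "tiny": GenerationProtocol(
            seed=seed, strains=("wild",), K_levels=(1.0,),
            t_grid=tuple(np.linspace(0.0, 1.0, 5)),
        ),
        "full": GenerationProtocol(seed=seed),
        "noisefree": GenerationProtocol(seed=seed, noise_level=0.0),
    }
    paths: dict[str, Path] = {}
    provenance = {}
    for name, proto in protocols.items():
        ds = generate(proto)
        path = outdir / f"kdp_dataset_{name}.csv"
        ds.write_csv(path)
        paths[name] = path
        provenance[name] = proto.describe()
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    paths["provenance"] = outdir / "provenance.json"
    return paths
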
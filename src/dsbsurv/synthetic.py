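"""Synthetic survival-table generator and the packaged cell-line registry.

The generator produces clonogenic tables with the model's own statistical
structure: the closed-form mean survival for each (dose, DMSO, oxygen) cell,
times multiplicative lognormal noise per replicate (clonogenic assays report
relative errors), truncated to (0, 1].  With zero noise the records equal
the closed-form predictions exactly, which makes every inference stage
testable by round-trip.

The registry ships the fitted per-cell-line parameters for CHO, AA8 and V79
(lethality probabilities and, where hypoxic data existed, the hypoxia
reduction factor) as a plain CSV fixture.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .model import (
    DEFAULT_SEED,
    LethalityParams,
    NucleusModel,
    analytic_mean_survival,
    n_loops,
)
from .modifiers import ScavengerModel, expected_dsb_hypoxic, expected_dsb_normoxic
from .inference import SurvivalDataset, SurvivalRecord

__all__ = [
    "GeneratorSpec",
    "CellLineEntry",
    "generate_dataset",
    "table1_registry",
    "get_cell_line",
]

#: Standard experimental design emulated by default: photon doses of a few
#: Gy up to the steep part of the curve, DMSO from none to saturating.
DEFAULT_DOSES = (2.0, 4.0, 8.0)
DEFAULT_CONCS = (0.0, 0.1, 0.5, 1.0)
DEFAULT_NOISE_SIGMA_LN = 0.05


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of a synthetic survival experiment."""

    lethality: LethalityParams
    cell_line: str = "SYNTH"
    nucleus: NucleusModel = NucleusModel()
    scavenger: ScavengerModel = ScavengerModel()
    hrf: float | None = None
    doses: tuple[float, ...] = DEFAULT_DOSES
    dmso_concs: tuple[float, ...] = DEFAULT_CONCS
    replicates: int = 1
    noise_sigma_ln: float = DEFAULT_NOISE_SIGMA_LN
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "dmso_concs", tuple(self.dmso_concs))
        if not self.doses:
            raise ValueError("doses must be non-empty")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.noise_sigma_ln < 0:
            raise ValueError(f"noise_sigma_ln must be >= 0, got {self.noise_sigma_ln}")
        if self.hrf is not None and self.hrf < 1:
            raise ValueError(f"hrf must be >= 1, got {self.hrf}")


def generate_dataset(spec: GeneratorSpec) -> SurvivalDataset:
    """Generate a survival table under ``spec``.

    Normoxic cells are always generated; hypoxic cells are added when
    ``spec.hrf`` is set.  Each replicate's surviving fraction is the
    analytic model mean times ``exp(N(0, noise_sigma_ln))``, truncated at 1.
    When noise is positive, records carry an absolute uncertainty of
    ``noise_sigma_ln`` times the surviving fraction (i.e. a relative
    uncertainty equal to the generating log-sigma), so the weighted
    log-domain objective sees homoscedastic residuals.  Reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ngl = n_loops(spec.nucleus)
    oxygen_states = ["normoxic"] + (["hypoxic"] if spec.hrf is not None else [])
    records: list[SurvivalRecord] = []
    for oxygen in oxygen_states:
        for dose in spec.doses:
            for conc in spec.dmso_concs:
                if oxygen == "normoxic":
                    mean_yield = expected_dsb_normoxic(
                        spec.nucleus, dose, conc, spec.scavenger
                    )
                else:
                    mean_yield = expected_dsb_hypoxic(
                        spec.nucleus, dose, conc, spec.hrf, spec.scavenger
                    )
                s_mean = analytic_mean_survival(mean_yield, ngl, spec.lethality)
                for _ in range(spec.replicates):
                    s = s_mean
                    if spec.noise_sigma_ln > 0:
                        s = s_mean * float(np.exp(rng.normal(0.0, spec.noise_sigma_ln)))
                    s = min(s, 1.0)
                    records.append(
                        SurvivalRecord(
                            cell_line=spec.cell_line,
                            dose=dose,
                            dmso_conc=conc,
                            oxygen=oxygen,
                            surviving_fraction=s,
                            uncertainty=(
                                spec.noise_sigma_ln * s
                                if spec.noise_sigma_ln > 0
                                else None
                            ),
                        )
                    )
    return SurvivalDataset(tuple(records))


@dataclass(frozen=True)
class CellLineEntry:
    """Registry entry: fitted lethality parameters and, if available, HRF."""

    lethality: LethalityParams
    hrf: float | None
    k_idsb_err: float | None = None
    k_cdsb_err: float | None = None
    reference: str = ""


def table1_registry() -> dict[str, CellLineEntry]:
    """Load the packaged per-cell-line parameter registry.

    Returns a mapping from cell-line name to its fitted lethality
    probabilities and hypoxia reduction factor (``hrf`` is ``None`` for
    lines without hypoxic measurements, e.g. V79).
    """
    registry: dict[str, CellLineEntry] = {}
    path = resources.files("dsbsurv.data").joinpath("cell_lines.csv")
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            hrf = row["hrf"].strip()
            registry[row["cell_line"]] = CellLineEntry(
                lethality=LethalityParams(
                    float(row["k_idsb"]), float(row["k_cdsb"])
                ),
                hrf=float(hrf) if hrf else None,
                k_idsb_err=float(row["k_idsb_err"]) if row["k_idsb_err"] else None,
                k_cdsb_err=float(row["k_cdsb_err"]) if row["k_cdsb_err"] else None,
                reference=row.get("reference", ""),
            )
    return registry


def get_cell_line(name: str) -> CellLineEntry:
    """Look up one registry entry; unknown names list the available lines."""
    registry = table1_registry()
    try:
        return registry[name]
    except KeyError:
        raise KeyError(
            f"unknown cell line {name!r}; available: {sorted(registry)}"
        ) from None
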
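"""Chemical modifiers of DSB induction: DMSO scavenging and the oxygen effect.

Only the indirect (radical-mediated) fraction of the DSB yield, ``1 - fr_dir``
of the total, responds to chemistry.  DMSO quenches OH radicals, scaling the
indirect yield by ``f_dmso = exp(-a * [DMSO]**b)``.  Hypoxia divides the total
yield by a hypoxia reduction factor (HRF, the DSB-level analogue of the
classical oxygen enhancement ratio); the direct-action term is assumed fully
oxygen-independent, so under hypoxia the scavengeable indirect yield is the
hypoxic total minus the unchanged direct part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import NucleusModel

__all__ = [
    "ScavengerModel",
    "OxygenModel",
    "ExposureCondition",
    "f_dmso",
    "hrf_from_o2",
    "alpha_hypoxic",
    "expected_dsb_normoxic",
    "expected_dsb_hypoxic",
    "r_dsb",
    "expected_dsb",
]


@dataclass(frozen=True)
class ScavengerModel:
    """DMSO scavenging parametrization and the direct-action fraction.

    ``f_dmso = exp(-a_dmso * c**b_dmso)`` with concentration ``c`` in molar;
    ``fr_dir`` is the cell-line-independent fraction of the DSB yield due to
    direct energy deposition on DNA (untouched by DMSO or oxygen).
    """

    a_dmso: float = 0.9065
    b_dmso: float = 0.4172
    fr_dir: float = 0.20

    def __post_init__(self) -> None:
        if not self.a_dmso > 0:
            raise ValueError(f"a_dmso must be > 0, got {self.a_dmso}")
        if not self.b_dmso > 0:
            raise ValueError(f"b_dmso must be > 0, got {self.b_dmso}")
        if not 0.0 <= self.fr_dir <= 1.0:
            raise ValueError(f"fr_dir must lie in [0, 1], got {self.fr_dir}")


@dataclass(frozen=True)
class OxygenModel:
    """HRF as a function of oxygen concentration (percent).

    ``hrf([O2]) = (m*k_turn + [O2]) / (k_turn + [O2])`` — a saturating
    hyperbola equal to ``m`` at full anoxia and approaching 1 at high [O2];
    ``k_turn`` is the half-effect (turning-point) concentration.
    """

    m: float = 2.94
    k_turn: float = 0.129

    def __post_init__(self) -> None:
        if not self.m >= 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if not self.k_turn > 0:
            raise ValueError(f"k_turn must be > 0, got {self.k_turn}")


@dataclass(frozen=True)
class ExposureCondition:
    """Dose + chemistry fully determining the expected DSB yield.

    Oxygen status is given in exactly one of three ways: normoxic (both
    ``hrf`` and ``o2_percent`` None), an explicit hypoxia reduction factor
    ``hrf``, or an oxygen concentration ``o2_percent`` to be resolved through
    an :class:`OxygenModel`.
    """

    dose: float
    dmso_conc: float = 0.0
    hrf: float | None = None
    o2_percent: float | None = None

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be nonnegative, got {self.dose} Gy")
        if self.dmso_conc < 0:
            raise ValueError(f"dmso_conc must be nonnegative, got {self.dmso_conc} M")
        if self.hrf is not None and self.o2_percent is not None:
            raise ValueError(
                "ambiguous oxygen specification: give either hrf or o2_percent, not both"
            )
        if self.hrf is not None and self.hrf < 1:
            raise ValueError(f"hrf must be >= 1, got {self.hrf}")
        if self.o2_percent is not None and self.o2_percent < 0:
            raise ValueError(f"o2_percent must be nonnegative, got {self.o2_percent}")

    @property
    def is_normoxic(self) -> bool:
        return self.hrf is None and self.o2_percent is None


def f_dmso(dmso_conc, model: ScavengerModel = ScavengerModel()):
    """Fraction of the indirect DSB yield surviving DMSO scavenging.

    ``exp(-a * c**b)``; exactly 1 at c = 0 (the continuous limit ``0**b = 0``
    for b > 0), decreasing toward 0 with concentration.  Accepts scalars or
    arrays.
    """
    c = np.asarray(dmso_conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("dmso_conc must be nonnegative")
    with np.errstate(divide="ignore"):
        out = np.exp(-model.a_dmso * np.where(c > 0, c, 0.0) ** model.b_dmso)
    out = np.where(c > 0, out, 1.0)
    if np.isscalar(dmso_conc):
        return float(out)
    return out


def hrf_from_o2(o2_percent, model: OxygenModel = OxygenModel()):
    """Hypoxia reduction factor at a given oxygen concentration in percent."""
    o2 = np.asarray(o2_percent, dtype=float)
    if np.any(o2 < 0):
        raise ValueError("o2_percent must be nonnegative")
    out = (model.m * model.k_turn + o2) / (model.k_turn + o2)
    if np.isscalar(o2_percent):
        return float(out)
    return out


def alpha_hypoxic(alpha_dsb: float, hrf: float) -> float:
    """Hypoxic DSB induction rate: the normoxic rate divided by the HRF."""
    if hrf < 1:
        raise ValueError(f"hrf must be >= 1 (got {hrf}); hypoxia cannot raise the DSB yield")
    return alpha_dsb / hrf


def expected_dsb_normoxic(
    nucleus: NucleusModel,
    dose: float,
    dmso_conc: float = 0.0,
    scavenger: ScavengerModel = ScavengerModel(),
) -> float:
    """Expected total DSB count under normoxia with DMSO.

    Direct term ``fr_dir * alpha * D * DNAc`` plus scavenged indirect term
    ``(1 - fr_dir) * alpha * D * DNAc * f_dmso``.  Reduces to the plain yield
    at zero DMSO.
    """
    if dose < 0:
        raise ValueError(f"dose must be nonnegative, got {dose} Gy")
    base = nucleus.alpha_dsb * dose * nucleus.dna_content
    f = f_dmso(dmso_conc, scavenger)
    return scavenger.fr_dir * base + (1.0 - scavenger.fr_dir) * base * f


def expected_dsb_hypoxic(
    nucleus: NucleusModel,
    dose: float,
    dmso_conc: float,
    hrf: float,
    scavenger: ScavengerModel = ScavengerModel(),
) -> float:
    """Expected total DSB count under hypoxia with DMSO.

    The HRF divides the total yield; the direct part is then restored
    unchanged and only the remainder (the hypoxic indirect yield,
    ``alpha/hrf - alpha*fr_dir``) is scavenged.  Requires
    ``hrf < 1/fr_dir`` so the indirect yield stays positive.
    """
    if dose < 0:
        raise ValueError(f"dose must be nonnegative, got {dose} Gy")
    if hrf < 1:
        raise ValueError(f"hrf must be >= 1, got {hrf}")
    if scavenger.fr_dir > 0 and hrf >= 1.0 / scavenger.fr_dir:
        raise ValueError(
            f"hrf = {hrf} violates the positivity constraint hrf < 1/fr_dir = "
            f"{1.0 / scavenger.fr_dir:g}: the hypoxic indirect yield "
            "alpha/hrf - alpha*fr_dir would be negative"
        )
    alpha = nucleus.alpha_dsb
    d_dnac = dose * nucleus.dna_content
    f = f_dmso(dmso_conc, scavenger)
    return scavenger.fr_dir * alpha * d_dnac + (alpha / hrf - alpha * scavenger.fr_dir) * d_dnac * f


def r_dsb(dmso_conc, scavenger: ScavengerModel = ScavengerModel()):
    """Relative normoxic DSB yield vs zero DMSO, in percent.

    ``(fr_dir + (1 - fr_dir) * f_dmso) * 100``: 100% at zero DMSO, saturating
    at ``fr_dir * 100`` (the direct-action floor) at high concentration.
    """
    f = f_dmso(dmso_conc, scavenger)
    out = (scavenger.fr_dir + (1.0 - scavenger.fr_dir) * np.asarray(f)) * 100.0
    if np.isscalar(dmso_conc):
        return float(out)
    return out


def expected_dsb(
    condition: ExposureCondition,
    nucleus: NucleusModel = NucleusModel(),
    scavenger: ScavengerModel = ScavengerModel(),
    oxygen_model: OxygenModel = OxygenModel(),
) -> float:
    """Expected DSB count for an arbitrary exposure condition.

    Dispatches to the normoxic or hypoxic yield; an oxygen concentration is
    first resolved to an HRF through ``oxygen_model``.
    """
    if condition.is_normoxic:
        return expected_dsb_normoxic(nucleus, condition.dose, condition.dmso_conc, scavenger)
    hrf = condition.hrf
    if hrf is None:
        hrf = hrf_from_o2(condition.o2_percent, oxygen_model)
    return expected_dsb_hypoxic(nucleus, condition.dose, condition.dmso_conc, hrf, scavenger)
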
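"""Mechanistic core of the giant-loop DSB cell-survival model.

Photon irradiation deposits dose homogeneously over the nucleus, inducing
double-strand breaks (DSBs) at a cell-line-independent rate ``alpha_dsb``
per Mbp per Gy.  The chromatin of the nucleus is partitioned into "giant
loops" of ~2 Mbp, the critical targets: a loop carrying exactly one DSB is
an *isolated* lesion (iDSB), a loop carrying two or more is a *complex*
lesion (cDSB).  Each lesion independently inactivates the cell with
probability ``k_idsb`` or ``k_cdsb``, so a cell with tally
(N_i, N_c) survives with probability

    S = (1 - k_idsb)**N_i * (1 - k_cdsb)**N_c

The population surviving fraction is the mean of S over stochastic damage
realizations.  Because per-loop break counts are i.i.d. Poisson with mean
``mu = <N_tot>/N_loops``, this mean also has the closed form implemented in
:func:`analytic_mean_survival`, used as a deterministic predictor for
fitting and as an exact oracle for the Monte Carlo path.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NucleusModel",
    "LethalityParams",
    "DamageTally",
    "SurvivalEstimate",
    "DEFAULT_SEED",
    "DEFAULT_N_SAMPLES",
    "n_loops",
    "expected_total_dsb",
    "sample_damage",
    "sample_damage_batch",
    "survival_probability",
    "mc_mean_survival",
    "analytic_mean_survival",
]

#: Default seed for all stochastic entry points (documented, reproducible).
DEFAULT_SEED = 20200514

#: Default number of Monte Carlo cells per survival estimate.
DEFAULT_N_SAMPLES = 10_000


@dataclass(frozen=True)
class NucleusModel:
    """Geometric/physical constants of the nucleus.

    Parameters
    ----------
    alpha_dsb
        DSB induction rate under normoxia, DSB / (Mbp Gy).
    dna_content
        Total DNA content of the nucleus, Mbp.
    loop_size
        DNA content of one giant loop, Mbp.
    """

    alpha_dsb: float = 5e-3
    dna_content: float = 6000.0
    loop_size: float = 2.0

    def __post_init__(self) -> None:
        if not self.alpha_dsb > 0:
            raise ValueError(f"alpha_dsb must be > 0, got {self.alpha_dsb}")
        if not self.dna_content > 0:
            raise ValueError(f"dna_content must be > 0, got {self.dna_content}")
        if not self.loop_size > 0:
            raise ValueError(f"loop_size must be > 0, got {self.loop_size}")


@dataclass(frozen=True)
class LethalityParams:
    """Per-lesion inactivation probabilities.

    ``k_idsb`` applies to isolated DSBs, ``k_cdsb`` to complex DSBs.  Both
    must lie in [0, 1]; ``k_idsb <= k_cdsb`` is physically expected (a
    complex lesion should be at least as lethal) and a warning is emitted
    when violated, but it is not enforced.
    """

    k_idsb: float
    k_cdsb: float

    def __post_init__(self) -> None:
        for name, value in (("k_idsb", self.k_idsb), ("k_cdsb", self.k_cdsb)):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.k_idsb > self.k_cdsb:
            warnings.warn(
                f"k_idsb ({self.k_idsb}) exceeds k_cdsb ({self.k_cdsb}); "
                "an isolated lesion should not be more lethal than a complex one",
                stacklevel=2,
            )


@dataclass(frozen=True)
class DamageTally:
    """One stochastic damage realization: total/isolated/complex DSB counts."""

    n_total: int
    n_isolated: int
    n_complex: int

    def __post_init__(self) -> None:
        for name, value in (
            ("n_total", self.n_total),
            ("n_isolated", self.n_isolated),
            ("n_complex", self.n_complex),
        ):
            if value < 0 or value != int(value):
                raise ValueError(f"{name} must be a nonnegative integer, got {value}")
        if self.n_isolated + 2 * self.n_complex > self.n_total:
            raise ValueError(
                f"inconsistent tally: n_isolated + 2*n_complex = "
                f"{self.n_isolated + 2 * self.n_complex} exceeds n_total = {self.n_total}"
            )


@dataclass(frozen=True)
class SurvivalEstimate:
    """Monte Carlo estimate of the population surviving fraction."""

    mean: float
    std_error: float
    n_samples: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError(f"mean surviving fraction must lie in [0, 1], got {self.mean}")
        if self.std_error < 0:
            raise ValueError(f"std_error must be nonnegative, got {self.std_error}")


def n_loops(nucleus: NucleusModel) -> int:
    """Number of giant loops in the nucleus, ``dna_content / loop_size``.

    The quotient must be integral (relative tolerance 1e-9): the loop
    partition is a physical tiling of the genome.
    """
    ratio = nucleus.dna_content / nucleus.loop_size
    nearest = round(ratio)
    if nearest < 1 or abs(ratio - nearest) > 1e-9 * ratio:
        raise ValueError(
            f"dna_content ({nucleus.dna_content} Mbp) is not an integer multiple "
            f"of loop_size ({nucleus.loop_size} Mbp)"
        )
    return int(nearest)


def expected_total_dsb(nucleus: NucleusModel, dose: float) -> float:
    """Expected total DSB count ``alpha_dsb * dose * dna_content`` (normoxia, no scavenger)."""
    if dose < 0:
        raise ValueError(f"dose must be nonnegative, got {dose} Gy")
    return nucleus.alpha_dsb * dose * nucleus.dna_content


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def sample_damage(expected_count: float, n_loops: int, rng_state=DEFAULT_SEED) -> DamageTally:
    """Draw one damage realization.

    The total break count is Poisson(``expected_count``); each break is then
    placed on a uniformly random loop, independently.  Loops with exactly one
    break are scored isolated, loops with two or more complex.
    """
    if expected_count < 0:
        raise ValueError(f"expected_count must be nonnegative, got {expected_count}")
    if n_loops < 1:
        raise ValueError(f"n_loops must be >= 1, got {n_loops}")
    rng = _as_rng(rng_state)
    n_total = int(rng.poisson(expected_count))
    if n_total == 0:
        return DamageTally(0, 0, 0)
    occupancy = np.bincount(rng.integers(0, n_loops, size=n_total), minlength=n_loops)
    return DamageTally(
        n_total=n_total,
        n_isolated=int(np.count_nonzero(occupancy == 1)),
        n_complex=int(np.count_nonzero(occupancy >= 2)),
    )


def sample_damage_batch(
    expected_count: float,
    n_loops: int,
    n_samples: int,
    rng_state=DEFAULT_SEED,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized damage sampling for ``n_samples`` independent cells.

    Returns ``(n_total, n_isolated, n_complex)`` integer arrays of length
    ``n_samples``.  Statistically identical to repeated :func:`sample_damage`
    (Poisson totals, uniform placement); occupancy is counted with a single
    sort over all breaks instead of a dense per-cell loop table so that large
    sample counts stay cheap.
    """
    if expected_count < 0:
        raise ValueError(f"expected_count must be nonnegative, got {expected_count}")
    if n_loops < 1:
        raise ValueError(f"n_loops must be >= 1, got {n_loops}")
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    rng = _as_rng(rng_state)
    n_total = rng.poisson(expected_count, size=n_samples)
    total_breaks = int(n_total.sum())
    if total_breaks == 0:
        zeros = np.zeros(n_samples, dtype=np.int64)
        return n_total.astype(np.int64), zeros, zeros.copy()
    loop_ids = rng.integers(0, n_loops, size=total_breaks, dtype=np.int64)
    cell_ids = np.repeat(np.arange(n_samples, dtype=np.int64), n_total)
    # one key per (cell, loop) pair; multiplicity = breaks on that loop
    keys, counts = np.unique(cell_ids * n_loops + loop_ids, return_counts=True)
    owner = keys // n_loops
    n_isolated = np.bincount(owner[counts == 1], minlength=n_samples)
    n_complex = np.bincount(owner[counts >= 2], minlength=n_samples)
    return n_total.astype(np.int64), n_isolated, n_complex


def survival_probability(tally: DamageTally, lethality: LethalityParams) -> float:
    """Survival probability of a single cell given its damage tally."""
    return (1.0 - lethality.k_idsb) ** tally.n_isolated * (
        1.0 - lethality.k_cdsb
    ) ** tally.n_complex


def mc_mean_survival(
    expected_count: float,
    n_loops: int,
    lethality: LethalityParams,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed=DEFAULT_SEED,
) -> SurvivalEstimate:
    """Monte Carlo population surviving fraction.

    Arithmetic mean of per-cell survival probabilities over ``n_samples``
    independent damage realizations.  Reproducible for a fixed ``seed``.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    _, n_iso, n_cpx = sample_damage_batch(expected_count, n_loops, n_samples, seed)
    s = (1.0 - lethality.k_idsb) ** n_iso * (1.0 - lethality.k_cdsb) ** n_cpx
    mean = float(s.mean())
    std_error = float(s.std(ddof=1) / math.sqrt(n_samples)) if n_samples > 1 else 0.0
    return SurvivalEstimate(mean=mean, std_error=std_error, n_samples=n_samples)


def analytic_mean_survival(
    expected_count,
    n_loops: int,
    lethality: LethalityParams,
):
    """Exact expectation of the Monte Carlo mean survival.

    Per-loop break counts are i.i.d. Poisson(``mu = expected_count/n_loops``),
    so the expected survival factorizes over loops:

        E[S] = [ e^-mu + (1-k_i) mu e^-mu + (1-k_c)(1 - e^-mu - mu e^-mu) ]^N_loops

    Accepts scalar or array ``expected_count``; evaluated in log space for
    numerical stability at large loop counts.
    """
    if n_loops < 1:
        raise ValueError(f"n_loops must be >= 1, got {n_loops}")
    mu = np.asarray(expected_count, dtype=float) / n_loops
    if np.any(mu < 0):
        raise ValueError("expected_count must be nonnegative")
    p0 = np.exp(-mu)
    p1 = mu * p0
    p_many = -np.expm1(-mu) - p1  # 1 - e^-mu - mu e^-mu, stable for small mu
    per_loop = p0 + (1.0 - lethality.k_idsb) * p1 + (1.0 - lethality.k_cdsb) * p_many
    out = np.exp(n_loops * np.log(per_loop))
    if np.isscalar(expected_count):
        return float(out)
    return out
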
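"""Parameter inference from clonogenic survival tables.

The fitting workflow proceeds in frozen stages, each consuming the output of
the previous one:

1. :func:`fit_lethality` — per-lesion inactivation probabilities
   ``(k_idsb, k_cdsb)`` from normoxic, zero-DMSO survival curves.
2. :func:`fit_hrf` — the hypoxia reduction factor from hypoxic zero-DMSO
   data, lethality held fixed.
3. :func:`fit_fdmso_points` — a free scavenging factor ``f`` per measured
   DMSO concentration, lethality (and HRF, if hypoxic) held fixed.
4. :func:`fit_fdmso_curve` — the two-parameter parametrization
   ``f = exp(-a c**b)`` through those points.

All fits use the closed-form mean survival as predictor, so they are
deterministic: no Monte Carlo noise enters inference.  The objective is
least squares on ``ln S`` (survival spans decades), inverse-variance
weighted when every record carries an uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import LethalityParams, NucleusModel, analytic_mean_survival, n_loops
from .modifiers import ScavengerModel

__all__ = [
    "SurvivalRecord",
    "SurvivalDataset",
    "FitResult",
    "objective",
    "fit_lethality",
    "fit_hrf",
    "fit_fdmso_points",
    "fit_fdmso_curve",
]

logger = logging.getLogger(__name__)

_OXYGEN_STATES = ("normoxic", "hypoxic")


@dataclass(frozen=True)
class SurvivalRecord:
    """One measured clonogenic data point."""

    cell_line: str
    dose: float
    dmso_conc: float
    oxygen: str
    surviving_fraction: float
    uncertainty: float | None = None

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be nonnegative, got {self.dose}")
        if self.dmso_conc < 0:
            raise ValueError(f"dmso_conc must be nonnegative, got {self.dmso_conc}")
        if self.oxygen not in _OXYGEN_STATES:
            raise ValueError(
                f"oxygen must be one of {_OXYGEN_STATES}, got {self.oxygen!r}"
            )
        if not 0.0 < self.surviving_fraction <= 1.0:
            raise ValueError(
                "surviving_fraction must lie in (0, 1] (log-domain fitting), "
                f"got {self.surviving_fraction}"
            )
        if self.uncertainty is not None and not self.uncertainty > 0:
            raise ValueError(f"uncertainty must be positive, got {self.uncertainty}")


@dataclass(frozen=True)
class SurvivalDataset:
    """An immutable collection of survival records; the unit of fitting."""

    records: tuple[SurvivalRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValueError("SurvivalDataset must contain at least one record")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def filter(self, **criteria) -> "SurvivalDataset":
        """Subset by exact field values, e.g. ``ds.filter(oxygen="normoxic")``."""
        kept = [
            r
            for r in self.records
            if all(getattr(r, k) == v for k, v in criteria.items())
        ]
        return SurvivalDataset(tuple(kept))

    @property
    def doses(self) -> np.ndarray:
        return np.array([r.dose for r in self.records])

    @property
    def dmso_concs(self) -> np.ndarray:
        return np.array([r.dmso_conc for r in self.records])

    @property
    def surviving_fractions(self) -> np.ndarray:
        return np.array([r.surviving_fraction for r in self.records])


@dataclass(frozen=True)
class FitResult:
    """Optimizer output: named estimates, approximate uncertainties, diagnostics.

    Uncertainties come from the local quadratic approximation of the
    objective at the optimum and are approximate; NaN where the curvature is
    not usable (e.g. at a bound).
    """

    params: dict[str, float]
    uncertainties: dict[str, float]
    objective: float
    converged: bool
    at_boundary: bool = False
    message: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.objective):
            raise ValueError(f"objective at optimum must be finite, got {self.objective}")
        for name, u in self.uncertainties.items():
            if np.isfinite(u) and u < 0:
                raise ValueError(f"uncertainty for {name} must be nonnegative, got {u}")


def objective(predicted, observed: SurvivalDataset) -> float:
    """Sum of squared log-survival residuals.

    ``sum w_i (ln pred_i - ln obs_i)**2`` with ``w_i = 1/sigma_ln_i**2`` when
    every record carries an uncertainty (absolute uncertainties are
    propagated to the log domain as relative ones, ``sigma_ln = u/S``);
    unweighted otherwise.
    """
    pred = np.asarray(predicted, dtype=float)
    if pred.shape != (len(observed),):
        raise ValueError(
            f"predicted has shape {pred.shape}, expected ({len(observed)},)"
        )
    if np.any(pred <= 0):
        return np.inf
    obs = observed.surviving_fractions
    resid = np.log(pred) - np.log(obs)
    uncertainties = [r.uncertainty for r in observed]
    if all(u is not None for u in uncertainties):
        sigma_ln = np.array(uncertainties) / obs
        resid = resid / sigma_ln
    return float(np.sum(resid**2))


def _hessian_uncertainties(
    fun, x_opt: np.ndarray, bounds, obj_value: float, n_obs: int, weighted: bool
) -> np.ndarray:
    """1-sigma uncertainties from the numerical Hessian of the objective.

    For a least-squares objective Q, cov = 2 s^2 H^{-1} with s^2 the residual
    variance (1 if the objective is already inverse-variance weighted).
    Returns NaN where the curvature is non-positive-definite or the optimum
    sits on a bound.
    """
    k = len(x_opt)
    nan = np.full(k, np.nan)
    h = 1e-5 * np.maximum(np.abs(x_opt), 1e-3)
    for i, (lo, hi) in enumerate(bounds):
        if x_opt[i] - h[i] < lo or x_opt[i] + h[i] > hi:
            return nan
    hess = np.empty((k, k))
    f0 = fun(x_opt)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                hess[i, i] = (fun(x_opt + ei) - 2 * f0 + fun(x_opt - ei)) / h[i] ** 2
            else:
                hess[i, j] = hess[j, i] = (
                    fun(x_opt + ei + ej)
                    - fun(x_opt + ei - ej)
                    - fun(x_opt - ei + ej)
                    + fun(x_opt - ei - ej)
                ) / (4 * h[i] * h[j])
    dof = max(n_obs - k, 1)
    s2 = 1.0 if weighted else max(obj_value, 0.0) / dof
    try:
        cov = 2.0 * s2 * np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return nan
    diag = np.diag(cov)
    return np.where(diag >= 0, np.sqrt(np.abs(diag)), np.nan)


def _is_weighted(dataset: SurvivalDataset) -> bool:
    return all(r.uncertainty is not None for r in dataset)


# ---------------------------------------------------------------- lethality


def fit_lethality(
    dataset: SurvivalDataset,
    nucleus: NucleusModel = NucleusModel(),
) -> FitResult:
    """Fit ``(k_idsb, k_cdsb)`` to a normoxic, zero-DMSO survival curve.

    Predictor: closed-form mean survival with the plain dose-proportional
    yield.  Both parameters are constrained to [0, 1].  A coarse grid
    pre-scan precedes bounded local optimization (the two lethalities trade
    off along a ridge at intermediate doses); ties break toward the lowest
    objective, then lexicographically smallest parameters.
    """
    for r in dataset:
        if r.oxygen != "normoxic":
            raise ValueError("lethality fitting requires normoxic records only")
        if r.dmso_conc != 0:
            raise ValueError("lethality fitting requires zero-DMSO records only")
    if len(set(r.dose for r in dataset)) < 3:
        raise ValueError(
            "lethality fitting requires at least 3 distinct doses, got "
            f"{sorted(set(r.dose for r in dataset))}"
        )
    ngl = n_loops(nucleus)
    yields = nucleus.alpha_dsb * dataset.doses * nucleus.dna_content
    weighted = _is_weighted(dataset)

    def q(x: np.ndarray) -> float:
        ki, kc = np.clip(x, 0.0, 1.0)
        pred = analytic_mean_survival(yields, ngl, LethalityParams(ki, kc))
        return objective(pred, dataset)

    # coarse pre-scan + documented fixed start
    starts = [np.array([1e-2, 0.5])]
    ki_grid = [0.0, 1e-3, 3e-3, 1e-2, 3e-2, 0.1]
    kc_grid = [0.1, 0.3, 0.5, 0.7, 0.9]
    grid = sorted(
        ((q(np.array([ki, kc])), ki, kc) for ki in ki_grid for kc in kc_grid),
        key=lambda t: (t[0], t[1], t[2]),
    )
    starts.extend(np.array([ki, kc]) for _, ki, kc in grid[:3])

    import warnings as _warnings

    best = None
    for x0 in starts:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # ki>kc transients during the search
            res = optimize.minimize(
                q, x0, method="L-BFGS-B", bounds=[(0.0, 1.0), (0.0, 1.0)]
            )
        key = (res.fun, res.x[0], res.x[1])
        if best is None or key < (best.fun, best.x[0], best.x[1]):
            best = res

    ki, kc = best.x
    at_boundary = bool(
        np.any(np.isclose(best.x, 0.0, atol=1e-9)) or np.any(np.isclose(best.x, 1.0))
    )
    unc = _hessian_uncertainties(
        q, best.x, [(0, 1), (0, 1)], best.fun, len(dataset), weighted
    )
    msg = "" if best.success else str(best.message)
    if at_boundary:
        msg = (msg + "; " if msg else "") + "optimum at a parameter bound"
    return FitResult(
        params={"k_idsb": float(ki), "k_cdsb": float(kc)},
        uncertainties={"k_idsb": float(unc[0]), "k_cdsb": float(unc[1])},
        objective=float(best.fun),
        converged=bool(best.success),
        at_boundary=at_boundary,
        message=msg,
    )


# ---------------------------------------------------------------- HRF


def fit_hrf(
    dataset: SurvivalDataset,
    lethality: LethalityParams,
    nucleus: NucleusModel = NucleusModel(),
    scavenger: ScavengerModel = ScavengerModel(),
) -> FitResult:
    """Fit the hypoxia reduction factor to hypoxic zero-DMSO data.

    One-dimensional bounded fit of ``hrf`` in ``[1, 1/fr_dir)`` with
    lethality held fixed; the predictor divides the DSB induction rate by
    the candidate HRF.
    """
    for r in dataset:
        if r.oxygen != "hypoxic":
            raise ValueError("HRF fitting requires hypoxic records only")
        if r.dmso_conc != 0:
            raise ValueError("HRF fitting requires zero-DMSO records only")
    ngl = n_loops(nucleus)
    base_yields = nucleus.alpha_dsb * dataset.doses * nucleus.dna_content
    weighted = _is_weighted(dataset)
    hi = 1.0 / scavenger.fr_dir - 1e-9 if scavenger.fr_dir > 0 else 100.0

    def q(hrf: float) -> float:
        pred = analytic_mean_survival(base_yields / hrf, ngl, lethality)
        return objective(pred, dataset)

    res = optimize.minimize_scalar(q, bounds=(1.0, hi), method="bounded")
    hrf = float(res.x)
    # bounded Brent (xatol ~1e-5) stops short of a bound it is pushing against
    at_boundary = hrf - 1.0 < 1e-4 or hi - hrf < 1e-4
    if at_boundary and hrf - 1.0 < 1e-4:
        # bounded Brent never reaches the bound exactly; snap when the
        # boundary value is at least as good
        if q(1.0) <= res.fun:
            hrf = 1.0
    unc = _hessian_uncertainties(
        lambda x: q(float(x[0])), np.array([hrf]), [(1.0, hi)], float(res.fun),
        len(dataset), weighted,
    )
    msg = "optimum at a parameter bound" if at_boundary else ""
    return FitResult(
        params={"hrf": hrf},
        uncertainties={"hrf": float(unc[0])},
        objective=float(q(hrf)),
        converged=bool(res.success),
        at_boundary=at_boundary,
        message=msg,
    )


# ---------------------------------------------------------------- fDMSO


def fit_fdmso_points(
    dataset: SurvivalDataset,
    lethality: LethalityParams,
    nucleus: NucleusModel = NucleusModel(),
    scavenger: ScavengerModel = ScavengerModel(),
    hrf: float | None = None,
) -> list[tuple[float, float]]:
    """Per-concentration scavenging factors.

    For each distinct DMSO concentration in the dataset, fits the scalar
    ``f`` in [0, 1] that replaces the parametrized ``f_dmso`` in the yield,
    minimizing the log-survival objective over all records at that
    concentration.  Records may be normoxic, or hypoxic with ``hrf`` given.
    Returns ``(concentration, f_estimate)`` pairs sorted by concentration.
    """
    hypoxic = [r for r in dataset if r.oxygen == "hypoxic"]
    if hypoxic and hrf is None:
        raise ValueError("dataset contains hypoxic records but no hrf was given")
    if hrf is not None:
        if hrf < 1:
            raise ValueError(f"hrf must be >= 1, got {hrf}")
        if scavenger.fr_dir > 0 and hrf >= 1.0 / scavenger.fr_dir:
            raise ValueError(
                f"hrf = {hrf} violates hrf < 1/fr_dir = {1.0 / scavenger.fr_dir:g}"
            )
    ngl = n_loops(nucleus)
    alpha = nucleus.alpha_dsb
    fr = scavenger.fr_dir
    out: list[tuple[float, float]] = []
    for conc in sorted(set(r.dmso_conc for r in dataset)):
        group = dataset.filter(dmso_conc=conc)
        d_dnac = group.doses * nucleus.dna_content
        hyp = np.array([r.oxygen == "hypoxic" for r in group])
        # direct term is oxygen-invariant; indirect rate differs
        indirect_rate = np.where(hyp, alpha / (hrf if hrf else 1.0) - alpha * fr, alpha * (1 - fr))

        def q(f: float) -> float:
            pred = analytic_mean_survival(
                fr * alpha * d_dnac + indirect_rate * d_dnac * f, ngl, lethality
            )
            return objective(pred, group)

        res = optimize.minimize_scalar(q, bounds=(0.0, 1.0), method="bounded")
        f_hat = float(np.clip(res.x, 0.0, 1.0))
        # bounded Brent stops short of the bounds; snap when a bound is at least as good
        for bound in (0.0, 1.0):
            if q(bound) <= q(f_hat):
                f_hat = bound
        out.append((float(conc), f_hat))
    return out


def fit_fdmso_curve(points: list[tuple[float, float]]) -> FitResult:
    """Fit the parametrization ``f = exp(-a c**b)`` to per-concentration points.

    Plain least squares on f-values; ``a`` and ``b`` constrained positive.
    Needs at least two distinct positive concentrations (points at c = 0
    carry no information on a, b and are ignored).
    """
    pos = [(c, f) for c, f in points if c > 0]
    if len(set(c for c, _ in pos)) < 2:
        raise ValueError(
            "curve fitting needs at least 2 distinct positive DMSO concentrations, "
            f"got {sorted(set(c for c, _ in pos))}"
        )
    c = np.array([p[0] for p in pos])
    f = np.array([p[1] for p in pos])

    def residuals(x: np.ndarray) -> np.ndarray:
        a, b = x
        return np.exp(-a * c**b) - f

    res = optimize.least_squares(
        residuals, x0=[1.0, 0.5], bounds=([0.0, 1e-12], [np.inf, np.inf])
    )
    a, b = res.x
    obj = float(2 * res.cost)
    # flat-gradient stall near a = 0: snap to the bound when the
    # no-scavenging model (f identically 1) is at least as good
    obj_zero = float(np.sum((1.0 - f) ** 2))
    if obj_zero <= obj + 1e-12:
        a, obj = 0.0, obj_zero
    at_boundary = a < 1e-8
    # covariance from the Gauss-Newton approximation J^T J
    unc = np.full(2, np.nan)
    if not at_boundary:
        try:
            jtj = res.jac.T @ res.jac
            dof = max(len(pos) - 2, 1)
            cov = np.linalg.inv(jtj) * obj / dof
            unc = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass
    return FitResult(
        params={"a_dmso": float(a), "b_dmso": float(b)},
        uncertainties={"a_dmso": float(unc[0]), "b_dmso": float(unc[1])},
        objective=obj,
        converged=bool(res.success),
        at_boundary=at_boundary,
        message="a at zero bound (no scavenging signal)" if at_boundary else "",
        extra={"n_points": len(pos)},
    )
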
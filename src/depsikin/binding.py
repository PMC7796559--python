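"""Coupled conformer/cation-binding equilibria and titration fitting.

The macrocycle exists in an asymmetric (A) and a symmetric (S) conformer
that interconvert independently of the salt; only the symmetric conformer
binds the monovalent cation M, forming a 1:1 complex SM and a 2:1 sandwich
S2M (two peptides, one cation)::

    A  <->  S          Kc  = [S] / [A]
    S + M  <-> SM      K1  = [SM] / ([S][M])
    SM + S <-> S2M     K2  = [S2M] / ([SM][S])

Observables along a titration at constant total peptide:

* the population-weighted chemical shift of a reporter proton of the
  symmetric species (all symmetric species are in fast exchange), and
* the asymmetric : total-symmetric conformer ratio from 1H integration,
  where the symmetric total counts peptide units: [S] + [SM] + 2[S2M].

A diagnostic consequence of the 2:1 species: with only free S and SM the
observed shift moves monotonically from delta_S towards delta_SM, so an
interior minimum (shift first drops, then rises at high salt) requires a
third symmetric species.  Conversely, the "lag" between the salt needed for
a 1:1 conformer ratio and the salt for a 50% shift change already arises
from the two coupled equilibria alone (conformer pre-equilibrium + 1:1
binding) and does not by itself indicate higher-order complexes.

Statistical-factor conventions (e.g. whether K2 carries a factor 2) are
absorbed into the fitted constants; concentrations are treated as
activities.  The asymmetric conformer is assumed non-binding with a
salt-independent shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import FitError, SpeciationError

__all__ = [
    "EquilibriumModel",
    "TitrationPoint",
    "SpeciationResult",
    "solve_speciation",
    "observed_shift",
    "conformer_ratio",
    "simulate_titration",
    "fit_titration",
    "TitrationFit",
    "lag_metric",
    "LagResult",
    "damped_logistic",
]

#: salt schedule (M) used in the titration experiments: 0-200 mM
DEFAULT_SALT_GRID_M = (0.0, 0.25e-3, 0.5e-3, 1e-3, 2e-3, 5e-3, 10e-3, 20e-3, 50e-3, 100e-3, 200e-3)
#: total peptide concentration (M) of the titration experiments
DEFAULT_PEPTIDE_M = 5e-3


@dataclass(frozen=True)
class EquilibriumModel:
    """Equilibrium constants and limiting shifts of the symmetric species.

    ``Kc`` (dimensionless) is the zero-salt [S]/[A] pre-equilibrium constant
    (``math.inf`` means no asymmetric conformer); ``K1`` (1/M) and ``K2``
    (1/M) are the stepwise 1:1 and 2:1 association constants; the deltas
    (ppm) are the limiting shifts of the reporter proton in free S, SM and
    S2M.
    """

    Kc: float
    K1: float
    K2: float
    delta_S: float = 0.0
    delta_SM: float = 0.0
    delta_S2M: float = 0.0

    def __post_init__(self) -> None:
        for name in ("Kc", "K1", "K2"):
            v = getattr(self, name)
            if not v >= 0:
                raise SpeciationError(f"{name} must be >= 0, got {v}")
        for name in ("delta_S", "delta_SM", "delta_S2M"):
            if not math.isfinite(getattr(self, name)):
                raise SpeciationError(f"{name} must be finite")


@dataclass(frozen=True)
class TitrationPoint:
    """One titration observation: totals plus optional observables."""

    P_total: float
    M_total: float
    delta_obs: float | None = None
    ratio_obs: float | None = None

    def __post_init__(self) -> None:
        if not self.P_total > 0:
            raise SpeciationError(f"P_total must be > 0, got {self.P_total}")
        if not self.M_total >= 0:
            raise SpeciationError(f"M_total must be >= 0, got {self.M_total}")


@dataclass(frozen=True)
class SpeciationResult:
    """Equilibrium concentrations (M) and mass-balance residuals."""

    conc_A: float
    conc_S: float
    conc_SM: float
    conc_S2M: float
    conc_M_free: float
    residual_peptide: float
    residual_ion: float

    @property
    def symmetric_total(self) -> float:
        """Peptide units in symmetric species: [S] + [SM] + 2[S2M]."""
        return self.conc_S + self.conc_SM + 2.0 * self.conc_S2M


def _solve_S(model: EquilibriumModel, P_total: float, m: float) -> float:
    """Free symmetric conformer at free-ion concentration m (closed form).

    Peptide balance  P = S/Kc + S + K1*S*m + 2*K1*K2*S^2*m  is quadratic in
    S with positive coefficients, so the positive root is unique.
    """
    inv_kc = 0.0 if math.isinf(model.Kc) else 1.0 / model.Kc
    a = 2.0 * model.K1 * model.K2 * m
    b = inv_kc + 1.0 + model.K1 * m
    if a > 0:
        # numerically stable positive root of a*S^2 + b*S - P = 0
        disc = math.sqrt(b * b + 4.0 * a * P_total)
        return 2.0 * P_total / (b + disc)
    return P_total / b


def solve_speciation(model: EquilibriumModel, P_total: float, M_total: float) -> SpeciationResult:
    """Solve the coupled mass balances for one titration point.

    The free-ion concentration is the single root variable, bracketed on
    ``[0, M_total]`` where the ion balance residual is monotone; the peptide
    sub-balance is solved in closed form inside the residual.  Deterministic.
    """
    if P_total < 0 or M_total < 0:
        raise SpeciationError("totals must be >= 0")
    if model.Kc == 0:
        if model.K1 > 0 or model.K2 > 0:
            raise SpeciationError(
                "Kc = 0 leaves no symmetric species, but K1/K2 > 0 requires them; "
                "set K1 = K2 = 0 for a purely asymmetric system"
            )
        return SpeciationResult(P_total, 0.0, 0.0, 0.0, M_total, 0.0, 0.0)

    def ion_residual(m: float) -> float:
        S = _solve_S(model, P_total, m)
        bound = model.K1 * S * m * (1.0 + model.K2 * S)
        return m + bound - M_total

    if M_total == 0 or model.K1 == 0:
        m = M_total if model.K1 == 0 else 0.0
    else:
        lo, hi = 0.0, M_total
        if ion_residual(hi) <= 0:
            m = hi
        else:
            m = brentq(ion_residual, lo, hi, xtol=1e-30, rtol=4 * np.finfo(float).eps)

    S = _solve_S(model, P_total, m)
    SM = model.K1 * S * m
    S2M = model.K2 * SM * S
    A = 0.0 if math.isinf(model.Kc) else S / model.Kc
    res_p = (A + S + SM + 2.0 * S2M) - P_total
    res_i = (m + SM + S2M) - M_total
    return SpeciationResult(A, S, SM, S2M, m, res_p, res_i)


def observed_shift(spec: SpeciationResult, model: EquilibriumModel) -> float:
    """Fast-exchange shift: population-weighted over symmetric peptide units.

    delta = (S*d_S + SM*d_SM + 2*S2M*d_S2M) / (S + SM + 2*S2M)
    """
    tot = spec.symmetric_total
    if tot <= 0:
        raise SpeciationError("observed shift undefined: no symmetric species present")
    return (
        spec.conc_S * model.delta_S
        + spec.conc_SM * model.delta_SM
        + 2.0 * spec.conc_S2M * model.delta_S2M
    ) / tot


def conformer_ratio(spec: SpeciationResult) -> float:
    """Asymmetric : total-symmetric ratio on a peptide-unit basis."""
    tot = spec.symmetric_total
    if tot <= 0:
        raise SpeciationError("conformer ratio undefined: no symmetric species present")
    return spec.conc_A / tot


def simulate_titration(
    model: EquilibriumModel,
    P_total: float = DEFAULT_PEPTIDE_M,
    salt_grid: tuple[float, ...] = DEFAULT_SALT_GRID_M,
) -> list[TitrationPoint]:
    """Noise-free titration curve: speciation + both observables per point."""
    points = []
    for m_tot in salt_grid:
        spec = solve_speciation(model, P_total, m_tot)
        points.append(
            TitrationPoint(
                P_total=P_total,
                M_total=m_tot,
                delta_obs=observed_shift(spec, model),
                ratio_obs=conformer_ratio(spec),
            )
        )
    return points


# ---------------------------------------------------------------------------
# fitting

_FITTABLE = ("Kc", "K1", "K2", "delta_S", "delta_SM", "delta_S2M")


@dataclass
class TitrationFit:
    """Best-fit model plus the degeneracy report.

    ``local_optima`` lists every distinct local optimum whose loss is within
    1% of the best -- titration data of this kind are notoriously
    under-determining, so several parameter sets may describe the data
    equally well and all of them are reported.
    """

    model: EquilibriumModel
    loss: float
    free_params: tuple[str, ...]
    stderr: dict[str, float | None]
    local_optima: list[tuple[EquilibriumModel, float]]
    n_multistart: int
    residuals: np.ndarray


def _titration_residuals(
    model: EquilibriumModel, data: list[TitrationPoint], ratio_weight: float
) -> np.ndarray:
    out = []
    for pt in data:
        spec = solve_speciation(model, pt.P_total, pt.M_total)
        if pt.delta_obs is not None:
            out.append(observed_shift(spec, model) - pt.delta_obs)
        if pt.ratio_obs is not None and ratio_weight > 0:
            r = conformer_ratio(spec)
            out.append(
                math.sqrt(ratio_weight)
                * (math.log(max(r, 1e-300)) - math.log(pt.ratio_obs))
            )
    return np.asarray(out)


def fit_titration(
    data: list[TitrationPoint],
    initial: EquilibriumModel,
    free_params: tuple[str, ...] = ("Kc", "K1", "K2", "delta_SM", "delta_S2M"),
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_multistart: int = 32,
    ratio_weight: float = 1.0,
) -> TitrationFit:
    """Weighted least squares over shift and/or log-ratio observables.

    The loss is ``sum(shift residuals^2) + ratio_weight * sum(log-ratio
    residuals^2)``.  ``n_multistart`` seeded restarts (initial values
    perturbed log-uniformly for constants, uniformly for shifts) expose fit
    degeneracy; all local optima within 1% of the best loss are reported.

    Raises ``FitError`` for non-identifiable requests, e.g. fitting
    ``delta_S2M`` while ``K2`` is fixed at zero.
    """
    import lmfit

    for p in free_params:
        if p not in _FITTABLE:
            raise FitError(f"unknown parameter {p!r}; fittable: {_FITTABLE}")
    if "delta_S2M" in free_params and "K2" not in free_params and initial.K2 == 0:
        raise FitError("delta_S2M is not identifiable while K2 is fixed at 0")
    if "delta_SM" in free_params and "K1" not in free_params and initial.K1 == 0:
        raise FitError("delta_SM is not identifiable while K1 is fixed at 0")
    n_obs = sum((pt.delta_obs is not None) + (pt.ratio_obs is not None) for pt in data)
    if n_obs < len(free_params):
        raise FitError(
            f"{n_obs} informative observations for {len(free_params)} free parameters"
        )

    bounds = bounds or {}
    shift_span = max(
        1.0,
        abs(initial.delta_SM - initial.delta_S),
        abs(initial.delta_S2M - initial.delta_S),
    )

    def make_params(start: EquilibriumModel) -> "lmfit.Parameters":
        params = lmfit.Parameters()
        for name in _FITTABLE:
            val = getattr(start, name)
            lo, hi = bounds.get(
                name,
                (0.0, math.inf) if name in ("Kc", "K1", "K2") else (-math.inf, math.inf),
            )
            params.add(name, value=val, vary=name in free_params, min=lo, max=hi)
        return params

    def residual(params: "lmfit.Parameters") -> np.ndarray:
        model = EquilibriumModel(**{n: params[n].value for n in _FITTABLE})
        return _titration_residuals(model, data, ratio_weight)

    rng = np.random.default_rng(seed)
    starts = [initial]
    for _ in range(max(0, n_multistart - 1)):
        kw = {}
        for name in _FITTABLE:
            val = getattr(initial, name)
            if name in free_params:
                if name in ("Kc", "K1", "K2"):
                    base = val if val > 0 else 1.0
                    kw[name] = base * 10 ** rng.uniform(-1.5, 1.5)
                else:
                    kw[name] = val + rng.uniform(-1.0, 1.0) * shift_span
            else:
                kw[name] = val
        starts.append(EquilibriumModel(**kw))

    fits = []
    for start in starts:
        try:
            out = lmfit.minimize(
                residual, make_params(start), method="leastsq", nan_policy="raise"
            )
        except (ValueError, SpeciationError):
            continue
        loss = float(np.sum(np.asarray(out.residual) ** 2))
        fits.append((out, loss))
    if not fits:
        raise FitError("all multistart fits failed")

    fits.sort(key=lambda t: t[1])
    best, best_loss = fits[0]
    best_model = EquilibriumModel(**{n: best.params[n].value for n in _FITTABLE})

    # collect distinct local optima within 1% of the best loss
    optima: list[tuple[EquilibriumModel, float]] = []
    for out, loss in fits:
        if loss > best_loss * 1.01 + 1e-30:
            continue
        m = EquilibriumModel(**{n: out.params[n].value for n in _FITTABLE})
        dup = False
        for m0, _ in optima:
            rel = [
                abs(getattr(m, n) - getattr(m0, n))
                / max(abs(getattr(m0, n)), 1e-12)
                for n in free_params
            ]
            if max(rel, default=0.0) < 0.05:
                dup = True
                break
        if not dup:
            optima.append((m, loss))

    stderr = {
        n: (float(best.params[n].stderr) if best.params[n].stderr is not None else None)
        for n in free_params
    }
    return TitrationFit(
        model=best_model,
        loss=best_loss,
        free_params=tuple(free_params),
        stderr=stderr,
        local_optima=optima,
        n_multistart=n_multistart,
        residuals=np.asarray(best.residual),
    )


# ---------------------------------------------------------------------------
# lag metric

@dataclass(frozen=True)
class LagResult:
    """Signed lag between the ratio and shift half-transition salt points."""

    lag: float | None
    salt_at_unit_ratio: float | None
    salt_at_half_shift: float | None
    reached: bool

    def __float__(self) -> float:
        if self.lag is None:
            raise SpeciationError("lag not reached on the searched salt grid")
        return self.lag


def lag_metric(
    model: EquilibriumModel,
    P_total: float = DEFAULT_PEPTIDE_M,
    salt_max: float = 10.0,
) -> LagResult:
    """Salt at (asym : sym ratio = 1) minus salt at 50% of total shift change.

    Both crossings are located by monotone bisection (``brentq``) on the
    exact simulated curves.  The shift half-point is defined against the
    total change between zero salt and ``salt_max``.  If the ratio never
    crosses 1 or the shift range is zero, the metric is flagged as not
    reached instead of raising.
    """

    def ratio_at(c: float) -> float:
        return conformer_ratio(solve_speciation(model, P_total, c))

    def shift_at(c: float) -> float:
        spec = solve_speciation(model, P_total, c)
        return observed_shift(spec, model)

    d0, d1 = shift_at(0.0), shift_at(salt_max)
    r0, r1 = ratio_at(0.0), ratio_at(salt_max)

    salt_ratio = None
    if r0 > 1.0 and r1 < 1.0:
        salt_ratio = brentq(lambda c: ratio_at(c) - 1.0, 0.0, salt_max, xtol=1e-15)
    elif r0 <= 1.0:
        salt_ratio = 0.0

    salt_shift = None
    if abs(d1 - d0) > 0:
        target = d0 + 0.5 * (d1 - d0)
        salt_shift = brentq(lambda c: shift_at(c) - target, 0.0, salt_max, xtol=1e-15)

    if salt_ratio is None or salt_shift is None:
        return LagResult(None, salt_ratio, salt_shift, False)
    return LagResult(salt_ratio - salt_shift, salt_ratio, salt_shift, True)


def damped_logistic(c, L, k, c0, d=0.0, y0=0.0):
    """Empirical damped logistic: ``y0 + L / (1 + exp(-k (c - c0))) / (1 + d c)``.

    A descriptive curve summary for saturating titration responses; reduces
    to the standard logistic at ``d = 0``.  The baseline ``y0`` accommodates
    the nonzero symmetric population at zero salt.  Requires ``d >= 0``.
    """
    c = np.asarray(c, float)
    if d < 0:
        raise FitError("damping coefficient d must be >= 0")
    return y0 + L / (1.0 + np.exp(-k * (c - c0))) / (1.0 + d * c)
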
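"""Structured antedependence (SAD) covariance structures.

A SAD model of order ``alpha`` writes the value of a random effect at
time point ``w_j`` as a regression on its ``alpha`` preceding values
plus an independent innovation::

    u(w_j) = sum_{s=1..alpha} theta_{s,j} * u(w_{j-s}) + e(w_j)

with ``e(w_j) ~ N(0, sigma2(w_j))``.  Both the antedependence
coefficients ``theta_{s,j}`` and the log innovation variance are
polynomial functions of the measurement time, so a handful of
coefficients describes a full, possibly non-stationary, covariance
matrix over the time grid.  Models are named ``SADa-b1..bA g`` after the
order ``a``, the per-lag polynomial degrees ``b_s`` and the innovation
log-variance degree ``g`` (e.g. ``SAD1-12``).

Two correlated effects (here: direct and indirect genetic effects) are
coupled through a cross-antedependence term: the first effect regresses
on the *same-week* value of the second in addition to its own lags,
with a time-polynomial coefficient ``delta_j``.

The implied covariance matrix of an effect over the grid is recovered
from the recursion matrices as ``Sigma = (L' D^-1 L)^-1`` where ``L`` is
unit lower triangular holding ``-theta`` terms and ``D`` is the diagonal
of innovation variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly

__all__ = [
    "TimeGrid",
    "PolyFn",
    "SADSpec",
    "CrossSADSpec",
    "EffectCovariance",
    "eval_poly",
    "innovation_variances",
    "build_L_D",
    "sigma_from_LD",
    "build_cross_sigma",
    "sigma_from_spec",
    "sample_effect",
    "sample_cross_effect",
    "project_sigma_to_sad",
    "project_sigma_to_cross_sad",
]

#: guard against exp() overflow in innovation variances
_MAX_LOG_VARIANCE = 300.0


@dataclass(frozen=True)
class TimeGrid:
    """Ordered measurement times, optionally affinely re-coded.

    Polynomials are evaluated at ``(w - shift) / scale`` so alternative
    time codings (centring, rescaling) can be tested without touching
    the polynomial coefficients.  The default is the raw week index.
    """

    weeks: tuple[float, ...]
    shift: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weeks, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("TimeGrid needs at least one time point")
        if np.any(np.diff(w) <= 0):
            raise ValueError("TimeGrid weeks must be strictly increasing")
        if self.scale == 0:
            raise ValueError("TimeGrid scale must be nonzero")
        object.__setattr__(self, "weeks", tuple(float(x) for x in w))

    @property
    def J(self) -> int:
        return len(self.weeks)

    @property
    def coded(self) -> np.ndarray:
        """Time values at which the polynomials are evaluated."""
        return (np.asarray(self.weeks) - self.shift) / self.scale


def default_grid(n_weeks: int = 5) -> TimeGrid:
    """Weekly grid 1..n_weeks (the fattening-period convention)."""
    return TimeGrid(tuple(range(1, n_weeks + 1)))


@dataclass(frozen=True)
class PolyFn:
    """Polynomial in time, constant term first."""

    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in np.atleast_1d(self.coefficients))
        if len(c) < 1:
            raise ValueError("PolyFn needs at least a constant term")
        object.__setattr__(self, "coefficients", c)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    @staticmethod
    def constant(value: float) -> "PolyFn":
        return PolyFn((float(value),))


def eval_poly(fn: PolyFn, grid: TimeGrid) -> np.ndarray:
    """Evaluate ``fn`` at every grid point: value_j = sum_q c_q w_j^q."""
    return npoly.polyval(grid.coded, np.asarray(fn.coefficients))


@dataclass(frozen=True)
class SADSpec:
    """SAD structure for a single random effect.

    Parameters
    ----------
    antedependence_fns
        One polynomial per lag ``s = 1..order`` giving ``theta_{s,j}``.
    innovation_logvar_fn
        Polynomial for the log innovation variance.
    """

    antedependence_fns: tuple[PolyFn, ...]
    innovation_logvar_fn: PolyFn

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "antedependence_fns", tuple(self.antedependence_fns)
        )

    @property
    def order(self) -> int:
        return len(self.antedependence_fns)

    @property
    def name(self) -> str:
        """Conventional SADa-b1..bA g model name, e.g. ``SAD1-12``."""
        degrees = "".join(str(f.degree) for f in self.antedependence_fns)
        return f"SAD{self.order}-{degrees}{self.innovation_logvar_fn.degree}"

    @property
    def n_params(self) -> int:
        return sum(f.degree + 1 for f in self.antedependence_fns) + (
            self.innovation_logvar_fn.degree + 1
        )


@dataclass(frozen=True)
class CrossSADSpec:
    """Correlated pair of SAD effects (direct and indirect genetic).

    The primary (direct) effect regresses on its own lags *and* on the
    same-week value of the secondary (indirect) effect through the
    cross-antedependence polynomial ``delta_j``; the secondary effect
    follows its own independent SAD recursion.
    """

    primary_spec: SADSpec
    secondary_spec: SADSpec
    cross_fn: PolyFn

    @property
    def name(self) -> str:
        return (
            f"{self.primary_spec.name}x{self.secondary_spec.name}"
            f"-d{self.cross_fn.degree}"
        )

    @property
    def n_params(self) -> int:
        return (
            self.primary_spec.n_params
            + self.secondary_spec.n_params
            + self.cross_fn.degree
            + 1
        )


@dataclass(frozen=True)
class EffectCovariance:
    """Labelled symmetric covariance matrix for an effect over the grid."""

    matrix: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if len(self.labels) != m.shape[0]:
            raise ValueError("label count must match matrix dimension")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", tuple(self.labels))


def innovation_variances(spec: SADSpec, grid: TimeGrid) -> np.ndarray:
    """Innovation variances exp(poly) at every grid point."""
    logvar = eval_poly(spec.innovation_logvar_fn, grid)
    if np.any(np.abs(logvar) > _MAX_LOG_VARIANCE):
        raise OverflowError(
            "innovation log-variance polynomial is extreme "
            f"(|log var| > {_MAX_LOG_VARIANCE}); check coefficients"
        )
    return np.exp(logvar)


def build_L_D(spec: SADSpec, grid: TimeGrid) -> tuple[np.ndarray, np.ndarray]:
    """Recursion matrices: unit lower-triangular L and diagonal D.

    ``L[j, j-s] = -theta_{s,j}`` for lags that exist (the recursion is
    truncated at the start of the grid where fewer than ``order``
    predecessors are available), ``D[j, j]`` is the innovation variance.
    """
    J = grid.J
    L = np.eye(J)
    thetas = [eval_poly(f, grid) for f in spec.antedependence_fns]
    for j in range(J):
        for s in range(1, min(spec.order, j) + 1):
            L[j, j - s] = -thetas[s - 1][j]
    D = np.diag(innovation_variances(spec, grid))
    return L, D


def sigma_from_LD(L: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Covariance implied by the recursion: ``(L' D^-1 L)^-1``.

    Equals the covariance of trajectories generated by running the
    recursion forward from ``u(w_1) = e(w_1)``.
    """
    d = np.diag(D)
    if np.any(d <= 0):
        raise ValueError("innovation variances must be strictly positive")
    # Sigma = L^-1 D L^-T; solve rather than invert the quadratic form
    Linv = np.linalg.inv(L)
    M = Linv @ np.diag(d) @ Linv.T
    return (M + M.T) / 2.0


def sigma_from_spec(spec: SADSpec, grid: TimeGrid) -> np.ndarray:
    """Convenience: covariance matrix implied by a single-effect spec."""
    L, D = build_L_D(spec, grid)
    return sigma_from_LD(L, D)


def _cross_L_D(
    spec: CrossSADSpec, grid: TimeGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Joint recursion matrices in the internal (IGE..., DGE...) order.

    The secondary (indirect) block comes first so that the primary
    (direct) rows can reference the same-week secondary value while L
    stays lower triangular.
    """
    J = grid.J
    L_p, D_p = build_L_D(spec.primary_spec, grid)
    L_s, D_s = build_L_D(spec.secondary_spec, grid)
    delta = eval_poly(spec.cross_fn, grid)
    L = np.zeros((2 * J, 2 * J))
    L[:J, :J] = L_s
    L[J:, J:] = L_p
    # direct effect at week j loads on the indirect effect at week j
    L[J + np.arange(J), np.arange(J)] = -delta
    D = np.zeros((2 * J, 2 * J))
    D[:J, :J] = D_s
    D[J:, J:] = D_p
    return L, D


def build_cross_sigma(spec: CrossSADSpec, grid: TimeGrid) -> np.ndarray:
    """Joint 2J x 2J covariance in block order [direct, indirect]."""
    J = grid.J
    L, D = _cross_L_D(spec, grid)
    sigma_si = sigma_from_LD(L, D)  # (IGE block, DGE block)
    perm = np.concatenate([np.arange(J, 2 * J), np.arange(J)])
    return sigma_si[np.ix_(perm, perm)]


def cross_effect_covariance(
    spec: CrossSADSpec, grid: TimeGrid
) -> EffectCovariance:
    labels = tuple(f"DGE_w{int(w)}" for w in grid.weeks) + tuple(
        f"IGE_w{int(w)}" for w in grid.weeks
    )
    return EffectCovariance(build_cross_sigma(spec, grid), labels)


def sample_effect(
    spec: SADSpec, grid: TimeGrid, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. trajectories by running the recursion forward."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    J = grid.J
    sd = np.sqrt(innovation_variances(spec, grid))
    thetas = [eval_poly(f, grid) for f in spec.antedependence_fns]
    out = np.empty((n, J))
    innov = rng.standard_normal((n, J)) * sd
    for j in range(J):
        val = innov[:, j].copy()
        for s in range(1, min(spec.order, j) + 1):
            val += thetas[s - 1][j] * out[:, j - s]
        out[:, j] = val
    return out


def sample_cross_effect(
    spec: CrossSADSpec, grid: TimeGrid, n: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the correlated pair; returns (direct, indirect) n x J arrays."""
    rng = np.random.default_rng(seed)
    J = grid.J
    indirect = sample_effect(spec.secondary_spec, grid, n, rng)
    sd = np.sqrt(innovation_variances(spec.primary_spec, grid))
    thetas = [
        eval_poly(f, grid) for f in spec.primary_spec.antedependence_fns
    ]
    delta = eval_poly(spec.cross_fn, grid)
    direct = np.empty((n, J))
    innov = rng.standard_normal((n, J)) * sd
    for j in range(J):
        val = innov[:, j] + delta[j] * indirect[:, j]
        for s in range(1, min(spec.primary_spec.order, j) + 1):
            val += thetas[s - 1][j] * direct[:, j - s]
        direct[:, j] = val
    return direct, indirect


# ---------------------------------------------------------------------------
# Projection of an arbitrary covariance onto a SAD structure.  Used for
# warm-starting REML and for round-trip testing: sequential regression of
# each time point on its predecessors recovers theta and the innovation
# variances, and polynomials are then fitted to those per-week values.


def _polyfit_coeffs(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    degree = min(degree, len(x) - 1)
    return npoly.polyfit(x, y, degree)


def decompose_sigma(
    sigma: np.ndarray, order: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-week antedependence coefficients and innovation variances.

    Regresses each time point on its ``min(order, j)`` predecessors
    under ``sigma``; returns ``theta`` (order x J, zero where the lag
    does not exist) and the innovation-variance vector.
    """
    sigma = np.asarray(sigma, dtype=float)
    J = sigma.shape[0]
    theta = np.zeros((order, J))
    d = np.zeros(J)
    d[0] = sigma[0, 0]
    for j in range(1, J):
        k = min(order, j)
        prev = np.arange(j - k, j)
        S_pp = sigma[np.ix_(prev, prev)]
        S_pj = sigma[prev, j]
        coef = np.linalg.solve(S_pp, S_pj)
        # coef is ordered oldest..newest; theta_s is the lag-s weight
        for s in range(1, k + 1):
            theta[s - 1, j] = coef[k - s]
        d[j] = sigma[j, j] - S_pj @ coef
    return theta, d


def project_sigma_to_sad(
    sigma: np.ndarray,
    grid: TimeGrid,
    order: int,
    ante_degrees: tuple[int, ...],
    logvar_degree: int,
) -> SADSpec:
    """Least-squares SAD approximation of an arbitrary covariance.

    The per-week regression coefficients and log innovation variances
    from :func:`decompose_sigma` are fitted with polynomials of the
    requested degrees.  Exact when ``sigma`` is itself SAD of the same
    structure; otherwise a sensible starting value for REML.
    """
    if len(ante_degrees) != order:
        raise ValueError("need one antedependence degree per lag")
    theta, d = decompose_sigma(sigma, order)
    t = grid.coded
    fns = []
    for s in range(order):
        # only weeks where lag s+1 exists inform the fit
        valid = np.arange(s + 1, grid.J)
        if len(valid) == 0:
            fns.append(PolyFn.constant(0.0))
            continue
        coeffs = _polyfit_coeffs(t[valid], theta[s, valid], ante_degrees[s])
        fns.append(PolyFn(tuple(coeffs)))
    lv = _polyfit_coeffs(t, np.log(np.maximum(d, 1e-12)), logvar_degree)
    return SADSpec(tuple(fns), PolyFn(tuple(lv)))


def project_sigma_to_cross_sad(
    sigma_joint: np.ndarray,
    grid: TimeGrid,
    order_primary: int,
    order_secondary: int,
    ante_degrees_primary: tuple[int, ...],
    ante_degrees_secondary: tuple[int, ...],
    cross_degree: int,
    logvar_degree_primary: int,
    logvar_degree_secondary: int,
) -> CrossSADSpec:
    """Cross-SAD approximation of a joint [direct, indirect] covariance.

    The indirect block is projected marginally; each direct week is then
    regressed on its own lags plus the same-week indirect value, and
    polynomials are fitted to the resulting coefficient profiles.
    """
    J = grid.J
    S = np.asarray(sigma_joint, dtype=float)
    if S.shape != (2 * J, 2 * J):
        raise ValueError("joint covariance must be 2J x 2J")
    dge = slice(0, J)
    ige = slice(J, 2 * J)
    secondary = project_sigma_to_sad(
        S[ige, ige], grid, order_secondary, ante_degrees_secondary,
        logvar_degree_secondary,
    )
    theta = np.zeros((order_primary, J))
    delta = np.zeros(J)
    d = np.zeros(J)
    for j in range(J):
        k = min(order_primary, j)
        own_prev = list(range(j - k, j))           # direct lags, oldest first
        preds = own_prev + [J + j]                 # plus same-week indirect
        S_pp = S[np.ix_(preds, preds)]
        S_pj = S[preds, j]
        coef = np.linalg.solve(S_pp, S_pj)
        for s in range(1, k + 1):
            theta[s - 1, j] = coef[k - s]
        delta[j] = coef[-1]
        d[j] = S[j, j] - S_pj @ coef
    t = grid.coded
    fns = []
    for s in range(order_primary):
        valid = np.arange(s + 1, J)
        if len(valid) == 0:
            fns.append(PolyFn.constant(0.0))
            continue
        fns.append(PolyFn(tuple(_polyfit_coeffs(
            t[valid], theta[s, valid], ante_degrees_primary[s]))))
    lv = _polyfit_coeffs(t, np.log(np.maximum(d, 1e-12)), logvar_degree_primary)
    primary = SADSpec(tuple(fns), PolyFn(tuple(lv)))
    cross = PolyFn(tuple(_polyfit_coeffs(t, delta, cross_degree)))
    return CrossSADSpec(primary, secondary, cross)
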
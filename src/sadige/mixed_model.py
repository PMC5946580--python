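"""Residual-free linear mixed model with SAD-structured random effects.

The phenotype model for a group-housed longitudinal trait is::

    y_ilm(w_j) = mu_i(w_j) + DGE_i(w_j) + sum_{k in mates(i)} IGE_k(w_j)
                 + l_l(w_j) + g_m(w_j) + p_i(w_j)

with correlated direct (DGE) and indirect (IGE) genetic effects
distributed ``N(0, A x Sigma_GE)`` over the pedigree, and independent
litter, group and pseudo-permanent effects with SAD-structured
week-by-week covariances.  There is no separate residual: the
pseudo-permanent animal effect absorbs it, which is why every record
carries a permanent term and the model stays full rank.

Estimation is REML over the low-dimensional vector of SAD polynomial
coefficients.  Internally the permanent effect plays the role of the
GLS residual (its covariance is block diagonal by animal), so the
restricted likelihood can be evaluated through sparse mixed-model
equations::

    -2 l_R = log|R| + log|G| + log|C| + y' P y   (+ const)

where ``C`` is the MME coefficient matrix.  This equals the dense-matrix
expression ``log|V| + log|X' V^-1 X| + y' P y`` exactly.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import minimize
from scipy.sparse.linalg import splu

from .pedigree import Pedigree, build_A_inverse, log_det_A
from .sad import (
    CrossSADSpec,
    PolyFn,
    SADSpec,
    TimeGrid,
    build_cross_sigma,
    eval_poly,
    sigma_from_spec,
)

__all__ = [
    "ModelSpec",
    "FitResult",
    "Design",
    "build_design",
    "reml_loglik",
    "fit_reml",
    "lrt",
    "predict_blup",
    "identifiability_diagnostics",
    "compute_information",
]


# ---------------------------------------------------------------------------
# model specification and parameter packing


@dataclass(frozen=True)
class ModelSpec:
    """Random- and fixed-effect structure of the model.

    ``genetic`` is a :class:`CrossSADSpec` (correlated DGE + IGE) or a
    plain :class:`SADSpec` (DGE only); ``None`` drops the genetic term
    entirely (useful for reduced/oracle models).  The permanent term is
    mandatory — it absorbs the residual.  ``fixed_factors`` are extra
    categorical phenotype columns added to the week-factor design.
    """

    grid: TimeGrid
    genetic: CrossSADSpec | SADSpec | None
    group: SADSpec | None
    permanent: SADSpec
    litter: SADSpec | None = None
    fixed_factors: tuple[str, ...] = ()

    @property
    def include_ige(self) -> bool:
        return isinstance(self.genetic, CrossSADSpec)

    @property
    def genetic_dim(self) -> int:
        """Per-animal genetic dimension: 2J with IGE, J without."""
        if self.genetic is None:
            return 0
        return (2 if self.include_ige else 1) * self.grid.J

    # -- parameter vector ---------------------------------------------------
    # Packing order (documented contract): genetic [primary antedependence,
    # secondary antedependence, cross, primary innovation, secondary
    # innovation], then group, litter, permanent; within each SADSpec the
    # antedependence polynomials come before the innovation log-variance,
    # each with coefficients in ascending degree order.

    def _spec_params(self, spec: SADSpec) -> list[float]:
        out: list[float] = []
        for f in spec.antedependence_fns:
            out.extend(f.coefficients)
        out.extend(spec.innovation_logvar_fn.coefficients)
        return out

    def pack(self) -> np.ndarray:
        out: list[float] = []
        if isinstance(self.genetic, CrossSADSpec):
            for f in self.genetic.primary_spec.antedependence_fns:
                out.extend(f.coefficients)
            for f in self.genetic.secondary_spec.antedependence_fns:
                out.extend(f.coefficients)
            out.extend(self.genetic.cross_fn.coefficients)
            out.extend(self.genetic.primary_spec.innovation_logvar_fn.coefficients)
            out.extend(self.genetic.secondary_spec.innovation_logvar_fn.coefficients)
        elif isinstance(self.genetic, SADSpec):
            out.extend(self._spec_params(self.genetic))
        for term in (self.group, self.litter, self.permanent):
            if term is not None:
                out.extend(self._spec_params(term))
        return np.asarray(out, dtype=float)

    @property
    def n_params(self) -> int:
        return len(self.pack())

    def unpack(self, omega: np.ndarray) -> "ModelSpec":
        """Rebuild the spec with coefficient values from ``omega``."""
        omega = np.asarray(omega, dtype=float)
        pos = 0

        def take(k: int) -> tuple[float, ...]:
            nonlocal pos
            vals = tuple(omega[pos : pos + k])
            pos += k
            return vals

        def take_fns(fns: tuple[PolyFn, ...]) -> tuple[PolyFn, ...]:
            return tuple(PolyFn(take(f.degree + 1)) for f in fns)

        def take_spec(spec: SADSpec) -> SADSpec:
            ante = take_fns(spec.antedependence_fns)
            lv = PolyFn(take(spec.innovation_logvar_fn.degree + 1))
            return SADSpec(ante, lv)

        genetic: CrossSADSpec | SADSpec | None
        if isinstance(self.genetic, CrossSADSpec):
            p_ante = take_fns(self.genetic.primary_spec.antedependence_fns)
            s_ante = take_fns(self.genetic.secondary_spec.antedependence_fns)
            cross = PolyFn(take(self.genetic.cross_fn.degree + 1))
            p_lv = PolyFn(
                take(self.genetic.primary_spec.innovation_logvar_fn.degree + 1)
            )
            s_lv = PolyFn(
                take(self.genetic.secondary_spec.innovation_logvar_fn.degree + 1)
            )
            genetic = CrossSADSpec(
                SADSpec(p_ante, p_lv), SADSpec(s_ante, s_lv), cross
            )
        elif isinstance(self.genetic, SADSpec):
            genetic = take_spec(self.genetic)
        else:
            genetic = None
        group = take_spec(self.group) if self.group is not None else None
        litter = take_spec(self.litter) if self.litter is not None else None
        permanent = take_spec(self.permanent)
        if pos != omega.size:
            raise ValueError(
                f"parameter vector has length {omega.size}, expected {pos}"
            )
        return replace(
            self, genetic=genetic, group=group, litter=litter,
            permanent=permanent,
        )

    # -- implied covariance matrices ---------------------------------------

    def genetic_sigma(self) -> np.ndarray | None:
        if self.genetic is None:
            return None
        if isinstance(self.genetic, CrossSADSpec):
            return build_cross_sigma(self.genetic, self.grid)
        return sigma_from_spec(self.genetic, self.grid)

    def covariance_matrices(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        g = self.genetic_sigma()
        if g is not None:
            out["genetic"] = g
        if self.group is not None:
            out["group"] = sigma_from_spec(self.group, self.grid)
        if self.litter is not None:
            out["litter"] = sigma_from_spec(self.litter, self.grid)
        out["permanent"] = sigma_from_spec(self.permanent, self.grid)
        return out


# ---------------------------------------------------------------------------
# design construction


@dataclass
class Design:
    """Incidence structures for one data set, reusable across parameter
    values (only covariance values change during REML iteration)."""

    y: np.ndarray
    X: np.ndarray
    Z: sparse.csr_matrix
    n_fixed: int
    n_ped: int
    genetic_dim: int
    n_groups: int
    n_litters: int
    grid: TimeGrid
    Ainv: sparse.csc_matrix | None
    logdet_A: float
    # permanent-effect (residual) structure: per observed-week pattern,
    # the record index array (n_animals_with_pattern, len(pattern))
    patterns: list[tuple[tuple[int, ...], np.ndarray]]
    animal_ids: tuple
    record_animal: np.ndarray
    record_week: np.ndarray
    fixed_names: tuple[str, ...]

    @property
    def n_records(self) -> int:
        return self.y.size

    @property
    def n_random(self) -> int:
        return self.Z.shape[1]


def _validate_records(records: pd.DataFrame, grid: TimeGrid) -> pd.DataFrame:
    required = {"animal", "group", "week", "adg"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    dup = records.duplicated(subset=["animal", "week"])
    if dup.any():
        row = records.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate record for animal {row['animal']!r} week {row['week']!r}"
        )
    weeks = set(float(w) for w in records["week"])
    if not weeks <= set(grid.weeks):
        raise ValueError(f"weeks {sorted(weeks - set(grid.weeks))} not on grid")
    return records


def build_design(
    records: pd.DataFrame, model: ModelSpec, ped: Pedigree | None
) -> Design:
    """Assemble fixed/random incidence matrices for the model.

    The IGE row of a record carries a 1 for each group mate with a
    record in the same group and week (the focal animal excluded), so
    incomplete cages automatically use the mates actually present.
    """
    records = _validate_records(records, model.grid).reset_index(drop=True)
    grid = model.grid
    J = grid.J
    week_pos = {float(w): j for j, w in enumerate(grid.weeks)}
    n = len(records)
    y = records["adg"].to_numpy(dtype=float)
    rec_week = np.asarray(
        [week_pos[float(w)] for w in records["week"]], dtype=np.int64
    )

    # fixed effects: week factor (full dummies) + extra factors (drop-first)
    X_parts = [np.eye(J)[rec_week]]
    fixed_names = [f"week_{int(w)}" for w in grid.weeks]
    for col in model.fixed_factors:
        if col not in records.columns:
            raise ValueError(f"fixed factor column {col!r} missing")
        dummies = pd.get_dummies(
            records[col].astype("category"), prefix=col, drop_first=True
        )
        X_parts.append(dummies.to_numpy(dtype=float))
        fixed_names.extend(dummies.columns)
    X = np.hstack(X_parts)

    gdim = model.genetic_dim
    if model.genetic is not None:
        if ped is None:
            raise ValueError("genetic term requires a pedigree")
        rec_animal = ped.index_of(records["animal"].tolist())
        n_ped = ped.n
        Ainv = build_A_inverse(ped)
        ldA = log_det_A(ped)
        animal_ids = ped.ids
    else:
        # no pedigree needed; index animals by appearance order
        uniq = pd.unique(records["animal"])
        lookup = {a: i for i, a in enumerate(uniq)}
        rec_animal = np.asarray([lookup[a] for a in records["animal"]])
        n_ped = len(uniq)
        Ainv, ldA = None, 0.0
        animal_ids = tuple(uniq)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add_block(r, c, v):
        rows.append(np.asarray(r, dtype=np.int64))
        cols.append(np.asarray(c, dtype=np.int64))
        vals.append(np.asarray(v, dtype=float))

    col_offset = 0
    if model.genetic is not None:
        # DGE: own animal x week
        add_block(np.arange(n), rec_animal * gdim + rec_week, np.ones(n))
        if model.include_ige:
            # IGE: each same-group same-week mate contributes
            grp = records.groupby(
                [records["group"], records["week"]], sort=False
            ).indices
            r_idx, c_idx = [], []
            for (_, _), members in grp.items():
                members = np.asarray(members)
                for m in members:
                    mates = members[members != m]
                    r_idx.append(np.full(len(mates), m))
                    c_idx.append(
                        rec_animal[mates] * gdim + J + rec_week[mates]
                    )
            if r_idx:
                r_all = np.concatenate(r_idx)
                c_all = np.concatenate(c_idx)
                add_block(r_all, c_all, np.ones(len(r_all)))
        col_offset += n_ped * gdim

    n_groups = 0
    if model.group is not None:
        group_ids = pd.unique(records["group"])
        g_lookup = {g: i for i, g in enumerate(group_ids)}
        g_idx = np.asarray([g_lookup[g] for g in records["group"]])
        n_groups = len(group_ids)
        add_block(
            np.arange(n), col_offset + g_idx * J + rec_week, np.ones(n)
        )
        col_offset += n_groups * J

    n_litters = 0
    if model.litter is not None:
        if "litter" not in records.columns:
            raise ValueError("litter term requires a 'litter' column")
        litter_ids = pd.unique(records["litter"])
        l_lookup = {v: i for i, v in enumerate(litter_ids)}
        l_idx = np.asarray([l_lookup[v] for v in records["litter"]])
        n_litters = len(litter_ids)
        add_block(
            np.arange(n), col_offset + l_idx * J + rec_week, np.ones(n)
        )
        col_offset += n_litters * J

    Z = sparse.csr_matrix(
        (
            np.concatenate(vals) if vals else np.zeros(0),
            (
                np.concatenate(rows) if rows else np.zeros(0, dtype=np.int64),
                np.concatenate(cols) if cols else np.zeros(0, dtype=np.int64),
            ),
        ),
        shape=(n, col_offset),
    )

    # permanent-effect (residual) block structure by observed-week pattern
    patterns: dict[tuple[int, ...], list[np.ndarray]] = {}
    order = np.argsort(rec_week, kind="stable")
    by_animal: dict[int, list[int]] = {}
    for r in order:
        by_animal.setdefault(int(rec_animal[r]), []).append(int(r))
    for recs in by_animal.values():
        pat = tuple(int(rec_week[r]) for r in recs)
        patterns.setdefault(pat, []).append(np.asarray(recs))
    pattern_list = [
        (pat, np.vstack(idx)) for pat, idx in sorted(patterns.items())
    ]

    return Design(
        y=y,
        X=X,
        Z=Z,
        n_fixed=X.shape[1],
        n_ped=n_ped,
        genetic_dim=gdim,
        n_groups=n_groups,
        n_litters=n_litters,
        grid=grid,
        Ainv=Ainv,
        logdet_A=ldA,
        patterns=pattern_list,
        animal_ids=animal_ids,
        record_animal=rec_animal,
        record_week=rec_week,
        fixed_names=tuple(fixed_names),
    )


# ---------------------------------------------------------------------------
# likelihood machinery


def _chol_inv_logdet(M: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant via Cholesky; raises on non-PD."""
    c = np.linalg.cholesky(M)
    inv = np.linalg.inv(M)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return (inv + inv.T) / 2.0, logdet


def _build_Rinv(
    design: Design, sigma_p: np.ndarray
) -> tuple[sparse.csr_matrix, float]:
    """Block-diagonal inverse of the permanent-effect covariance.

    One block per animal, restricted to its observed weeks.
    """
    n = design.n_records
    rows, cols, vals = [], [], []
    logdet = 0.0
    for pat, idx in design.patterns:
        sub = sigma_p[np.ix_(pat, pat)]
        S, ld = _chol_inv_logdet(sub)
        m, k = idx.shape
        logdet += m * ld
        rows.append(np.repeat(idx, k, axis=1).ravel())
        cols.append(np.tile(idx, (1, k)).ravel())
        vals.append(np.tile(S.ravel(), m))
    Rinv = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return Rinv, logdet


def _build_Ginv(
    design: Design, model: ModelSpec
) -> tuple[sparse.csc_matrix | None, float]:
    """Inverse covariance of the explicit random effects, and log|G|."""
    blocks = []
    logdet = 0.0
    if model.genetic is not None:
        sigma_ge = model.genetic_sigma()
        Sinv, ld = _chol_inv_logdet(sigma_ge)
        blocks.append(sparse.kron(design.Ainv, Sinv, format="csc"))
        logdet += design.n_ped * ld + design.genetic_dim * design.logdet_A
    if model.group is not None:
        Sg, ld = _chol_inv_logdet(sigma_from_spec(model.group, model.grid))
        blocks.append(
            sparse.kron(sparse.eye(design.n_groups), Sg, format="csc")
        )
        logdet += design.n_groups * ld
    if model.litter is not None:
        Sl, ld = _chol_inv_logdet(sigma_from_spec(model.litter, model.grid))
        blocks.append(
            sparse.kron(sparse.eye(design.n_litters), Sl, format="csc")
        )
        logdet += design.n_litters * ld
    if not blocks:
        return None, 0.0
    return sparse.block_diag(blocks, format="csc"), logdet


@dataclass
class _MMESolution:
    """Internal: factorized mixed-model equations at one parameter value."""

    loglik: float
    sol: np.ndarray        # [fixed effects, random effect solutions]
    rhs: np.ndarray
    lu: object
    Rinv: sparse.csr_matrix
    logdet_R: float
    logdet_G: float
    logdet_C: float
    yPy: float


def _solve_mme(design: Design, model: ModelSpec) -> _MMESolution:
    sigma_p = sigma_from_spec(model.permanent, model.grid)
    Rinv, logdet_R = _build_Rinv(design, sigma_p)
    Ginv, logdet_G = _build_Ginv(design, model)

    X = sparse.csr_matrix(design.X)
    W = sparse.hstack([X, design.Z], format="csr")
    WtR = W.T @ Rinv
    p = design.n_fixed
    if Ginv is not None:
        C = (WtR @ W + sparse.block_diag(
            [sparse.csc_matrix((p, p)), Ginv], format="csc"
        )).tocsc()
    else:
        C = (WtR @ W).tocsc()
    rhs = WtR @ design.y
    lu = splu(C, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True})
    diagU = lu.U.diagonal()
    if np.any(diagU == 0):
        raise np.linalg.LinAlgError("singular mixed-model equations")
    logdet_C = float(np.sum(np.log(np.abs(diagU))))
    sol = lu.solve(rhs)
    yRy = float(design.y @ (Rinv @ design.y))
    yPy = yRy - float(rhs @ sol)
    n, pfix = design.n_records, design.n_fixed
    const = -0.5 * (n - pfix) * np.log(2.0 * np.pi)
    ll = -0.5 * (logdet_R + logdet_G + logdet_C + yPy) + const
    return _MMESolution(
        loglik=ll, sol=sol, rhs=rhs, lu=lu, Rinv=Rinv,
        logdet_R=logdet_R, logdet_G=logdet_G, logdet_C=logdet_C, yPy=yPy,
    )


def reml_loglik(
    omega: np.ndarray, design: Design, model: ModelSpec
) -> float:
    """Restricted log-likelihood at parameter vector ``omega``.

    Returns ``-inf`` for parameter values implying a non-positive
    definite permanent-effect covariance (the likelihood is undefined
    there), so optimizers treat the region as infeasible.
    """
    try:
        m = model.unpack(omega)
        return _solve_mme(design, m).loglik
    except (np.linalg.LinAlgError, OverflowError, FloatingPointError):
        return -np.inf


# ---------------------------------------------------------------------------
# REML fitting


@dataclass
class FitResult:
    """REML estimates with provenance of the optimization."""

    model: ModelSpec
    estimates: np.ndarray
    reml_loglik: float
    converged: bool
    n_evaluations: int
    trace: list[float]
    info_matrix: np.ndarray | None = None
    elapsed_seconds: float = 0.0
    at_boundary: bool = False

    @property
    def n_params(self) -> int:
        return self.estimates.size

    @property
    def fitted_model(self) -> ModelSpec:
        return self.model.unpack(self.estimates)

    def covariance_matrices(self) -> dict[str, np.ndarray]:
        return self.fitted_model.covariance_matrices()

    @property
    def param_covariance(self) -> np.ndarray:
        """H = inverse information; sampling covariance of the estimates."""
        if self.info_matrix is None:
            raise ValueError("information matrix was not computed for this fit")
        return np.linalg.pinv(self.info_matrix)


def _default_start(model: ModelSpec, y: np.ndarray) -> np.ndarray:
    """Crude variance split as a generic starting point.

    Splits the phenotypic variance evenly over the variance-bearing
    terms (constant log innovation variance), zero antedependence.
    """
    omega = np.zeros(model.n_params)
    start = model.unpack(omega)
    vy = max(float(np.var(y)), 1e-6)
    n_terms = sum(
        t is not None
        for t in (start.genetic, start.group, start.litter, start.permanent)
    )
    share = np.log(vy / max(n_terms, 1))

    def set_const_logvar(spec: SADSpec) -> SADSpec:
        c = list(spec.innovation_logvar_fn.coefficients)
        c[0] = share
        return SADSpec(spec.antedependence_fns, PolyFn(tuple(c)))

    genetic = start.genetic
    if isinstance(genetic, CrossSADSpec):
        genetic = CrossSADSpec(
            set_const_logvar(genetic.primary_spec),
            SADSpec(
                genetic.secondary_spec.antedependence_fns,
                PolyFn(
                    (share - np.log(49.0),)
                    + (0.0,) * genetic.secondary_spec.innovation_logvar_fn.degree
                ),
            ),
            genetic.cross_fn,
        )
    elif isinstance(genetic, SADSpec):
        genetic = set_const_logvar(genetic)
    group = set_const_logvar(start.group) if start.group is not None else None
    litter = set_const_logvar(start.litter) if start.litter is not None else None
    permanent = set_const_logvar(start.permanent)
    return replace(
        start, genetic=genetic, group=group, litter=litter, permanent=permanent
    ).pack()


#: an innovation variance this far below the phenotypic scale marks a
#: boundary solution (the parameter drifting to -inf on the log scale)
_BOUNDARY_LOG_FLOOR = np.log(1e-4)


def optimize_reml(
    loglik_fn,
    model: ModelSpec,
    y: np.ndarray,
    init: np.ndarray | str | None = None,
    tol: float = 1e-6,
    max_evaluations: int = 500,
    restarts: int = 2,
    restart_tol: float = 0.1,
) -> FitResult:
    """Shared REML optimizer over a log-likelihood callable.

    L-BFGS-B with up to ``restarts`` additional cold restarts (each
    restart rebuilds the curvature memory, which helps markedly in the
    long curved valleys these likelihoods exhibit).  The fit is
    declared converged when a restart improves the restricted
    likelihood by less than ``restart_tol`` (or the optimizer reports
    interior convergence); solutions whose innovation variances
    collapse toward zero are additionally flagged ``at_boundary``.
    Used by both the general sparse-MME likelihood and the fast nucleus
    likelihood (same parameterization, identical restricted
    likelihood).
    """
    if isinstance(init, str) and init == "ladder":
        omega0 = _ladder_start(loglik_fn, model, y)
    elif init is None:
        omega0 = _default_start(model, y)
    else:
        omega0 = np.asarray(init, dtype=float)
        if omega0.size != model.n_params:
            raise ValueError("init has wrong length")

    trace: list[float] = []
    n_eval = [0]

    def objective(omega: np.ndarray) -> float:
        n_eval[0] += 1
        ll = loglik_fn(omega)
        trace.append(ll)
        return 1e12 if not np.isfinite(ll) else -ll

    t0 = time.perf_counter()
    om = omega0
    prev_ll = -np.inf
    converged = False
    res = None
    for stage in range(restarts + 1):
        res = minimize(
            objective,
            om,
            method="L-BFGS-B",
            options={
                "maxfun": max_evaluations,
                # scipy's ftol is relative to |f|; the likelihood is
                # O(1e4), so 1e-11 corresponds to ~1e-7 absolute change
                "ftol": 1e-11,
                "gtol": tol * 10,
                "eps": 3e-5,
                "maxcor": 25,
            },
        )
        om = np.asarray(res.x, dtype=float)
        ll_now = -res.fun
        if res.success or (
            np.isfinite(prev_ll) and ll_now - prev_ll < restart_tol
        ):
            converged = np.isfinite(ll_now)
            break
        prev_ll = ll_now
    if model.n_params <= 8:
        # low-dimensional fits: derivative-free polish past the
        # finite-difference accuracy floor
        res = minimize(
            objective, om, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxfev": 150},
        )
        if -res.fun >= -objective(om):
            om = np.asarray(res.x, dtype=float)
        converged = converged or res.success
    elapsed = time.perf_counter() - t0
    finite = [v for v in trace if np.isfinite(v)]
    ll_hat = -res.fun if np.isfinite(res.fun) else (max(finite) if finite else -np.inf)
    fitted = model.unpack(om)
    at_boundary = _hits_variance_floor(fitted, float(np.var(y)))
    return FitResult(
        model=model,
        estimates=om,
        reml_loglik=float(ll_hat),
        converged=converged and np.isfinite(ll_hat),
        n_evaluations=n_eval[0],
        trace=trace,
        elapsed_seconds=elapsed,
        at_boundary=at_boundary,
    )


def _hits_variance_floor(fitted: ModelSpec, var_y: float) -> bool:
    """True when any innovation variance collapses to ~zero relative to
    the phenotypic scale — a boundary of the parameter space."""
    floor = _BOUNDARY_LOG_FLOOR + np.log(max(var_y, 1e-12))
    specs: list[SADSpec] = []
    g = fitted.genetic
    if isinstance(g, CrossSADSpec):
        specs += [g.primary_spec, g.secondary_spec]
    elif isinstance(g, SADSpec):
        specs.append(g)
    specs += [t for t in (fitted.group, fitted.litter, fitted.permanent) if t]
    for spec in specs:
        logvar = eval_poly(spec.innovation_logvar_fn, fitted.grid)
        if np.any(logvar < floor):
            return True
    return False


def fit_reml(
    records: pd.DataFrame,
    model: ModelSpec,
    ped: Pedigree | None,
    init: np.ndarray | str | None = None,
    tol: float = 1e-6,
    max_evaluations: int = 500,
    compute_info: bool = False,
    design: Design | None = None,
) -> FitResult:
    """Maximize the restricted likelihood over the SAD coefficients.

    ``init`` may be an explicit parameter vector, ``None`` (crude
    variance split), or ``"ladder"`` to warm-start from a fit of the
    reduced order-0/degree-0 structure.  Non-convergence is reported
    through ``converged``, never as an exception.
    """
    if design is None:
        design = build_design(records, model, ped)

    def ll(omega: np.ndarray) -> float:
        return reml_loglik(omega, design, model)

    fit = optimize_reml(ll, model, design.y, init, tol, max_evaluations)
    if compute_info:
        fit.info_matrix = compute_information(design, model, fit.estimates)
    return fit


def _ladder_start(loglik_fn, model: ModelSpec, y: np.ndarray) -> np.ndarray:
    """Warm-start ladder: fit the reduced constant-coefficient model.

    First rung: all polynomials reduced to their constant terms
    (stationary antedependence and innovation variances, constant cross
    term) — optimized over that subspace.  The full-degree optimization
    then starts from the embedded rung-1 solution.  Complex SAD fits
    converge much more reliably from such a reduced solution than from
    arbitrary values.
    """
    base = _default_start(model, y)
    free = _constant_term_indices(model)
    if isinstance(model.genetic, CrossSADSpec):
        # hold the indirect-effect and cross constants at their prior
        # scale during the first rung: the reduced stationary model
        # otherwise absorbs the (small) indirect variance into the
        # group term and strands the full fit at that boundary
        ige_own = _ige_and_cross_indices(model)
        free = np.asarray([i for i in free if i not in set(ige_own)])

    def obj(sub: np.ndarray) -> float:
        om = base.copy()
        om[free] = sub
        ll = loglik_fn(om)
        return 1e12 if not np.isfinite(ll) else -ll

    res = minimize(
        obj, base[free], method="L-BFGS-B",
        options={"maxfun": 300, "ftol": 1e-10, "gtol": 1e-4, "eps": 1e-5},
    )
    out = base.copy()
    out[free] = res.x
    return out


def _ige_and_cross_indices(model: ModelSpec) -> np.ndarray:
    """Positions of all indirect-effect and cross-term coefficients."""
    g = model.genetic
    if not isinstance(g, CrossSADSpec):
        return np.zeros(0, dtype=np.int64)
    pos = sum(f.degree + 1 for f in g.primary_spec.antedependence_fns)
    idx = []
    for f in g.secondary_spec.antedependence_fns:
        idx.extend(range(pos, pos + f.degree + 1))
        pos += f.degree + 1
    idx.extend(range(pos, pos + g.cross_fn.degree + 1))
    pos += g.cross_fn.degree + 1
    pos += g.primary_spec.innovation_logvar_fn.degree + 1
    idx.extend(
        range(pos, pos + g.secondary_spec.innovation_logvar_fn.degree + 1)
    )
    return np.asarray(idx, dtype=np.int64)


def _constant_term_indices(model: ModelSpec) -> np.ndarray:
    """Positions of the constant term of every polynomial in omega."""
    idx: list[int] = []
    pos = 0

    def take_fn(f: PolyFn) -> None:
        nonlocal pos
        idx.append(pos)
        pos += f.degree + 1

    def walk_spec(spec: SADSpec) -> None:
        for f in spec.antedependence_fns:
            take_fn(f)
        take_fn(spec.innovation_logvar_fn)

    g = model.genetic
    if isinstance(g, CrossSADSpec):
        for f in g.primary_spec.antedependence_fns:
            take_fn(f)
        for f in g.secondary_spec.antedependence_fns:
            take_fn(f)
        take_fn(g.cross_fn)
        take_fn(g.primary_spec.innovation_logvar_fn)
        take_fn(g.secondary_spec.innovation_logvar_fn)
    elif isinstance(g, SADSpec):
        walk_spec(g)
    for term in (model.group, model.litter, model.permanent):
        if term is not None:
            walk_spec(term)
    return np.asarray(idx, dtype=np.int64)


# ---------------------------------------------------------------------------
# inference utilities


def lrt(fit_full: FitResult, fit_reduced: FitResult) -> tuple[float, int]:
    """Likelihood-ratio statistic and df for nested REML fits."""
    stat = 2.0 * (fit_full.reml_loglik - fit_reduced.reml_loglik)
    df = fit_full.n_params - fit_reduced.n_params
    if stat < -1e-6:
        raise ValueError(
            f"negative LRT statistic ({stat:.3g}): a fit failed to converge"
        )
    return max(stat, 0.0), df


def compute_information(
    design: Design,
    model: ModelSpec,
    omega: np.ndarray,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Observed information: minus the central-difference Hessian of the
    restricted log-likelihood at ``omega``."""
    return information_from_loglik(
        lambda om: reml_loglik(om, design, model), omega, rel_step
    )


def information_from_loglik(
    f, omega: np.ndarray, rel_step: float = 1e-4
) -> np.ndarray:
    """Central-difference observed information for any REML likelihood."""
    omega = np.asarray(omega, dtype=float)
    k = omega.size
    h = rel_step * np.maximum(np.abs(omega), 1.0)

    f0 = f(omega)
    H = np.zeros((k, k))
    fp = np.zeros(k)
    fm = np.zeros(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = h[i]
        fp[i] = f(omega + e)
        fm[i] = f(omega - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            e_i = np.zeros(k)
            e_j = np.zeros(k)
            e_i[i] = h[i]
            e_j[j] = h[j]
            fpp = f(omega + e_i + e_j)
            fmm = f(omega - e_i - e_j)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm
            ) / (2.0 * h[i] * h[j])
    return -H


@dataclass
class BlupResult:
    """Mixed-model-equation solutions at fixed variance components."""

    fixed_effects: pd.Series
    ebv: pd.DataFrame           # animal, week, dge_ebv [, ige_ebv]
    group_effects: np.ndarray
    litter_effects: np.ndarray
    permanent_effects: pd.DataFrame
    solution: np.ndarray
    design: Design


def predict_blup(
    records: pd.DataFrame,
    model: ModelSpec,
    ped: Pedigree | None,
    omega: np.ndarray,
    design: Design | None = None,
) -> BlupResult:
    """BLUP of all random effects at fixed (known) variance components.

    Animals present in the pedigree but without records receive EBVs
    through the relationship matrix.  The permanent-effect solutions are
    recovered from the GLS residual as ``Sigma_p R^-1 (y - X b - Z u)``
    restricted to each animal's observed weeks.
    """
    m = model.unpack(np.asarray(omega, dtype=float))
    if design is None:
        design = build_design(records, m, ped)
    if np.linalg.matrix_rank(design.X) < design.n_fixed:
        raise ValueError("fixed-effect design is rank deficient (aliasing)")
    sol = _solve_mme(design, m)
    p = design.n_fixed
    fixed = pd.Series(sol.sol[:p], index=design.fixed_names)
    u = sol.sol[p:]
    J = design.grid.J
    gdim = design.genetic_dim
    ebv = pd.DataFrame()
    if m.genetic is not None:
        g = u[: design.n_ped * gdim].reshape(design.n_ped, gdim)
        recs = {
            "animal": np.repeat(design.animal_ids, J),
            "week": np.tile([int(w) for w in design.grid.weeks], design.n_ped),
            "dge_ebv": g[:, :J].ravel(),
        }
        if m.include_ige:
            recs["ige_ebv"] = g[:, J:].ravel()
        ebv = pd.DataFrame(recs)
    off = design.n_ped * gdim
    grp = u[off : off + design.n_groups * J].reshape(design.n_groups, J)
    off += design.n_groups * J
    lit = u[off : off + design.n_litters * J].reshape(design.n_litters, J)

    # permanent-effect BLUP: Sigma_p[pat] @ Sigma_p[pat]^-1 @ resid — the
    # GLS residual itself, since the permanent term absorbs the residual
    resid = design.y - design.X @ sol.sol[:p] - design.Z @ u
    perm_rows = [(pat, idx, resid[idx]) for pat, idx in design.patterns]
    perm = pd.DataFrame(
        {
            "record": np.concatenate([i.ravel() for _, i, _ in perm_rows]),
            "p_hat": np.concatenate([v.ravel() for _, _, v in perm_rows]),
        }
    ).sort_values("record")

    return BlupResult(
        fixed_effects=fixed,
        ebv=ebv,
        group_effects=grp,
        litter_effects=lit,
        permanent_effects=perm,
        solution=sol.sol,
        design=design,
    )


def identifiability_diagnostics(
    fit: FitResult, submatrix: np.ndarray | None = None
) -> dict:
    """Condition number sqrt(l_max/l_min) of the information matrix and
    the correlation matrix of the estimates from H = I^-1.

    Large condition numbers signal weakly identified parameter
    combinations; correlations above ~0.6 in absolute value flag pairs
    the data cannot separate.
    """
    if fit.info_matrix is None:
        raise ValueError("fit has no information matrix")
    info = fit.info_matrix

    def cond(M: np.ndarray) -> float:
        ev = np.linalg.eigvalsh(M)
        if ev[-1] <= 0:
            return np.inf
        return float(np.sqrt(ev[-1] / ev[0])) if ev[0] > 0 else np.inf

    H = np.linalg.pinv(info)
    sd = np.sqrt(np.maximum(np.diag(H), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = H / np.outer(sd, sd)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    np.fill_diagonal(corr, 1.0)
    out = {
        "condition_number": cond(info),
        "estimate_correlations": corr,
        "flagged_pairs": [
            (i, j)
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[1])
            if abs(corr[i, j]) > 0.6
        ],
        "psd": bool(np.all(np.linalg.eigvalsh(info) > -1e-8 * np.trace(info))),
    }
    if submatrix is not None:
        sub = info[np.ix_(submatrix, submatrix)]
        out["submatrix_condition_number"] = cond(sub)
    return out
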
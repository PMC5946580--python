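"""Fast REML for the balanced nucleus design (reduced animal model).

The base-cohort fits of the selection and parameter-recovery studies
have a very regular structure: unrelated, unphenotyped founder parents;
complete cages of ``K`` phenotyped offspring with all ``J`` weekly
records; week-factor fixed effects; genetic + group + permanent random
effects.  For that structure the offsprings' Mendelian sampling
deviations can be integrated out analytically, leaving mixed-model
equations over the founders only.

Writing an offspring's genetic trajectory as the parent average plus an
independent Mendelian deviation ``m_i ~ N(0, Sigma_GE / 2)``, the
phenotype becomes parent-mean regression plus a cage-local error that
collects Mendelian, group and permanent terms.  Records of one cage are
then jointly normal with an identical ``KJ x KJ`` covariance block per
cage built from two J x J blocks:

    diagonal   B_d = Sigma_DD/2 + (K-1) Sigma_II/2 + Sigma_p + Sigma_g
    off-diag   B_o = (Sigma_DI + Sigma_DI')/2 + (K-2) Sigma_II/2 + Sigma_g

so the "residual" covariance is block diagonal by cage and the only
genetic unknowns left are the founders' direct/indirect trajectories
with prior ``I x Sigma_GE``.  The equations shrink from ~10 per animal
in the pedigree to ~10 per founder, and the coefficient-matrix
assembly is fully precomputed: per evaluation only numeric values are
recomputed (batched per-cage contractions scattered onto a fixed
sparsity pattern) followed by one small sparse factorization.

The value computed here is *identical* to the general sparse-MME
restricted likelihood (same marginal model); the agreement is verified
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .mixed_model import (
    FitResult,
    ModelSpec,
    information_from_loglik,
    optimize_reml,
)
from .sad import CrossSADSpec, sigma_from_spec

__all__ = ["NucleusDesign", "build_nucleus_design", "nucleus_reml_loglik",
           "fit_nucleus_reml"]


@dataclass
class NucleusDesign:
    """Precomputed incidence and scatter structures (see module docs).

    The design matrix is represented cage-wise through per-animal
    loadings on "column groups" (the week-factor block plus one
    direct and one indirect block per parent present in the cage);
    weeks expand diagonally, so one contraction per cage yields every
    coefficient-matrix contribution.
    """

    y: np.ndarray                  # cage-major record order
    y_cage: np.ndarray             # (n_cages, K*J)
    loadings: np.ndarray           # (n_cages, K, Gmax)
    colbase: np.ndarray            # (n_cages, Gmax) base C column of block
    n_cols: int                    # dimension of the MME
    n_cages: int
    group_size: int
    J: int
    n_parents: int
    include_ige: bool
    # fixed CSC pattern of the coefficient matrix and value scatter maps
    csc_indices: np.ndarray
    csc_indptr: np.ndarray
    sandwich_map: np.ndarray       # valid sandwich entries -> data slot
    sandwich_valid: np.ndarray     # boolean mask over raw entries
    prior_map: np.ndarray          # genetic-prior entries -> data slot
    rhs_map: np.ndarray            # (n_cages*Gmax*J) -> rhs slot (or -1)

    @property
    def n_records(self) -> int:
        return self.y.size

    @property
    def gdim(self) -> int:
        return (2 if self.include_ige else 1) * self.J


def build_nucleus_design(
    records: pd.DataFrame,
    model: ModelSpec,
    sire_of: dict,
    dam_of: dict,
) -> NucleusDesign:
    """Assemble the reduced-animal-model design.

    ``sire_of`` / ``dam_of`` map each phenotyped animal id to its
    (founder) parent id.  Requirements checked: complete cages of equal
    size, a full week grid per animal, no litter term and week-only
    fixed effects; parents are assumed unphenotyped, unrelated and
    non-inbred, which is the construction of the nucleus base cohort.
    """
    if model.litter is not None or model.fixed_factors:
        raise ValueError("nucleus fast path supports week-only fixed effects")
    if model.genetic is None or model.group is None:
        raise ValueError("nucleus fast path needs genetic and group terms")
    J = model.grid.J
    recs = records.sort_values(
        ["group", "animal", "week"], kind="stable"
    ).reset_index(drop=True)
    n = len(recs)
    if n % J:
        raise ValueError("every animal needs a full week grid")
    animals = recs["animal"].to_numpy()[::J]
    groups = recs["group"].to_numpy()[::J]
    counts = pd.Series(groups).value_counts()
    K = int(counts.iloc[0])
    if not (counts == K).all():
        raise ValueError("cages must all have the same size")
    if np.any(recs["week"].to_numpy().reshape(-1, J) !=
              np.asarray(model.grid.weeks)[None, :]):
        raise ValueError("records must cover the full week grid per animal")
    n_cages = len(counts)
    include_ige = model.include_ige
    gdim = (2 if include_ige else 1) * J

    parents: dict = {}
    for a in animals:
        for p in (sire_of[a], dam_of[a]):
            parents.setdefault(p, len(parents))
    n_par = len(parents)
    n_cols = J + n_par * gdim

    # per-cage column groups and loadings
    eff_per_parent = 2 if include_ige else 1
    Gmax = 1 + eff_per_parent * 2 * K  # upper bound (distinct parents)
    cage_ids = pd.unique(groups)
    loadings = np.zeros((n_cages, K, Gmax))
    colbase = np.full((n_cages, Gmax), -1, dtype=np.int64)
    members_of = {g: [] for g in cage_ids}
    for a, g in zip(animals, groups):
        members_of[g].append(a)
    g_used = 0
    for c, g in enumerate(cage_ids):
        mem = members_of[g]
        # group 0: week-factor fixed effects
        colbase[c, 0] = 0
        loadings[c, :, 0] = 1.0
        local: dict = {}
        for ai, a in enumerate(mem):
            for p in (sire_of[a], dam_of[a]):
                if (p, "D") not in local:
                    gi = 1 + len(local)
                    local[(p, "D")] = gi
                    colbase[c, gi] = J + parents[p] * gdim
                    if include_ige:
                        gi2 = 1 + len(local)
                        local[(p, "I")] = gi2
                        colbase[c, gi2] = J + parents[p] * gdim + J
                loadings[c, ai, local[(p, "D")]] += 0.5
        if include_ige:
            for ai, a in enumerate(mem):
                for mate in mem:
                    if mate == a:
                        continue
                    for p in (sire_of[mate], dam_of[mate]):
                        loadings[c, ai, local[(p, "I")]] += 0.5
        g_used = max(g_used, 1 + len(local))
    loadings = loadings[:, :, :g_used]
    colbase = colbase[:, :g_used]
    Gmax = g_used

    # raw sandwich entry (c, g, w, h, v) -> C position (row, col)
    valid_g = colbase >= 0                                  # (c, G)
    wv = np.arange(J)
    shape5 = (n_cages, Gmax, J, Gmax, J)
    gw = colbase[:, :, None] + wv[None, None, :]            # (c, G, J)
    rows = np.broadcast_to(gw[:, :, :, None, None], shape5).ravel()
    cols = np.broadcast_to(gw[:, None, None, :, :], shape5).ravel()
    valid = np.broadcast_to(
        valid_g[:, :, None, None, None]
        & valid_g[:, None, None, :, None],
        shape5,
    ).ravel()

    # genetic-prior entries: kron(I_par, Sigma_GE^-1)
    gi, gj = np.meshgrid(np.arange(gdim), np.arange(gdim), indexing="ij")
    p_rows = (
        J + np.arange(n_par)[:, None, None] * gdim + gi[None]
    ).ravel()
    p_cols = (
        J + np.arange(n_par)[:, None, None] * gdim + gj[None]
    ).ravel()

    all_rows = np.concatenate([rows[valid], p_rows])
    all_cols = np.concatenate([cols[valid], p_cols])
    key = all_cols.astype(np.int64) * n_cols + all_rows
    uniq, inverse = np.unique(key, return_inverse=True)
    csc_indices = (uniq % n_cols).astype(np.int32)
    uc = uniq // n_cols
    csc_indptr = np.zeros(n_cols + 1, dtype=np.int32)
    np.add.at(csc_indptr, uc + 1, 1)
    csc_indptr = np.cumsum(csc_indptr).astype(np.int32)
    n_sand = int(valid.sum())
    sandwich_map = inverse[:n_sand].astype(np.int64)
    prior_map = inverse[n_sand:].astype(np.int64)

    # rhs scatter: (c, g, w) -> column index (or -1 for padding)
    rhs_map = np.where(
        valid_g[:, :, None],
        colbase[:, :, None] + wv[None, None, :],
        -1,
    ).ravel()

    y = recs["adg"].to_numpy(dtype=float)
    return NucleusDesign(
        y=y,
        y_cage=y.reshape(n_cages, K * J),
        loadings=loadings,
        colbase=colbase,
        n_cols=n_cols,
        n_cages=n_cages,
        group_size=K,
        J=J,
        n_parents=n_par,
        include_ige=include_ige,
        csc_indices=csc_indices,
        csc_indptr=csc_indptr,
        sandwich_map=sandwich_map,
        sandwich_valid=valid,
        prior_map=prior_map,
        rhs_map=rhs_map,
    )


def _cage_residual_blocks(
    model: ModelSpec, K: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(B_diag, B_off, Sigma_GE): the within-cage error covariance
    blocks after integrating out Mendelian deviations."""
    J = model.grid.J
    sigma_ge = model.genetic_sigma()
    sigma_g = sigma_from_spec(model.group, model.grid)
    sigma_p = sigma_from_spec(model.permanent, model.grid)
    if model.include_ige:
        S_dd = sigma_ge[:J, :J]
        S_di = sigma_ge[:J, J:]
        S_ii = sigma_ge[J:, J:]
    else:
        S_dd = sigma_ge
        S_di = np.zeros((J, J))
        S_ii = np.zeros((J, J))
    B_diag = 0.5 * S_dd + (K - 1) * 0.5 * S_ii + sigma_p + sigma_g
    B_off = 0.5 * (S_di + S_di.T) + (K - 2) * 0.5 * S_ii + sigma_g
    return B_diag, B_off, sigma_ge


def nucleus_reml_loglik(
    omega: np.ndarray, design: NucleusDesign, model: ModelSpec
) -> float:
    """Restricted log-likelihood via the reduced animal model."""
    try:
        m = model.unpack(omega)
        K, J = design.group_size, design.J
        B_d, B_o, sigma_ge = _cage_residual_blocks(m, K)
        Rc = np.kron(np.eye(K), B_d - B_o) + np.kron(np.ones((K, K)), B_o)
        cR = np.linalg.cholesky(Rc)
        Rc_inv = np.linalg.inv(Rc)
        Rc_inv = (Rc_inv + Rc_inv.T) / 2.0
        logdet_R = design.n_cages * 2.0 * float(
            np.sum(np.log(np.diag(cR)))
        )

        cG = np.linalg.cholesky(sigma_ge)
        Sg_inv = np.linalg.inv(sigma_ge)
        Sg_inv = (Sg_inv + Sg_inv.T) / 2.0
        logdet_G = design.n_parents * 2.0 * float(
            np.sum(np.log(np.diag(cG)))
        )

        # batched sandwich: T[c,g,w,h,v] = sum_ab M[c,a,g] Rcinv[aw,bv] M[c,b,h]
        Ml = design.loadings
        R4 = Rc_inv.reshape(K, J, K, J)
        half = np.einsum("cag,awbv->cgwbv", Ml, R4, optimize=True)
        T = np.einsum("cgwbv,cbh->cgwhv", half, Ml, optimize=True)
        Tvals = T.ravel()[design.sandwich_valid]

        nnz = design.csc_indices.size
        data = np.bincount(
            design.sandwich_map, weights=Tvals, minlength=nnz
        ).astype(float)
        prior_vals = np.tile(Sg_inv.ravel(), design.n_parents)
        np.add.at(data, design.prior_map, prior_vals)

        C = sparse.csc_matrix(
            (data, design.csc_indices, design.csc_indptr),
            shape=(design.n_cols, design.n_cols),
        )

        # rhs: W' R^-1 y via the same cage contraction
        Q = design.y_cage.reshape(design.n_cages, K, J)
        RinvY = np.einsum("awbv,cbv->caw", R4, Q, optimize=True)
        rhs_contrib = np.einsum("cag,caw->cgw", Ml, RinvY, optimize=True)
        rhs = np.zeros(design.n_cols)
        ok = design.rhs_map >= 0
        np.add.at(rhs, design.rhs_map[ok], rhs_contrib.ravel()[ok])
        yRy = float(np.einsum("caw,caw->", Q, RinvY))

        lu = splu(
            C, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True}
        )
        diagU = lu.U.diagonal()
        if np.any(diagU == 0):
            return -np.inf
        logdet_C = float(np.sum(np.log(np.abs(diagU))))
        sol = lu.solve(rhs)
        yPy = yRy - float(rhs @ sol)
        const = -0.5 * (design.n_records - J) * np.log(2.0 * np.pi)
        return -0.5 * (logdet_R + logdet_G + logdet_C + yPy) + const
    except (np.linalg.LinAlgError, OverflowError, FloatingPointError):
        return -np.inf


def fit_nucleus_reml(
    records: pd.DataFrame,
    model: ModelSpec,
    sire_of: dict,
    dam_of: dict,
    init: np.ndarray | str | None = "moments",
    tol: float = 1e-6,
    max_evaluations: int = 500,
    restarts: int = 2,
    restart_tol: float = 0.1,
    compute_info: bool = False,
) -> FitResult:
    """REML on the nucleus base cohort via the reduced animal model.

    The default start is the method-of-moments projection
    (:func:`moment_start`); ``"ladder"`` and explicit vectors are also
    accepted.
    """
    design = build_nucleus_design(records, model, sire_of, dam_of)
    if isinstance(init, str) and init == "moments":
        init = moment_start(records, model, sire_of, dam_of)

    def ll(omega: np.ndarray) -> float:
        return nucleus_reml_loglik(omega, design, model)

    fit = optimize_reml(
        ll, model, design.y, init, tol, max_evaluations,
        restarts=restarts, restart_tol=restart_tol,
    )
    if compute_info:
        fit.info_matrix = information_from_loglik(ll, fit.estimates)
    return fit


# ---------------------------------------------------------------------------
# method-of-moments pre-estimation (REML starting values)

# expected-relatedness coefficients of the pair classes used by
# moment_start, columns = [S_DD, sym S_DI, S_II, Sigma_g, Sigma_p]:
# self; cage mate of a different family; in-cage full sib; out-of-cage
# full sib; non-family cage mate of an out-of-cage full sib.  The
# chunked cage assignment (a chunk of four families fills four cages)
# makes sib cages share the same companion families, which is where
# the large indirect coefficients of the last two classes come from.
# rows: self; cage mate diff family; in-cage sib; out-of-cage sib;
# out-of-cage paternal half sib; non-family cage mate of out-of-cage sib
_MOMENT_COEFFS = np.array(
    [
        [1.0, 1.0, 10.0, 1.0, 1.0],
        [0.0, 3.0, 9.0, 1.0, 0.0],
        [0.5, 2.0, 9.5, 1.0, 0.0],
        [0.5, 1.0, 6.5, 0.0, 0.0],
        [0.25, 0.5, 0.25, 0.0, 0.0],
        [0.0, 2.0, 6.0, 0.0, 0.0],
    ]
)


def _psd_floor(M: np.ndarray, rel: float = 1e-3) -> np.ndarray:
    """Clip eigenvalues from below at ``rel`` x mean diagonal."""
    M = (M + M.T) / 2.0
    floor = rel * max(float(np.trace(M)) / M.shape[0], 1e-6)
    w, V = np.linalg.eigh(M)
    return V @ np.diag(np.maximum(w, floor)) @ V.T


def moment_covariances(
    records: pd.DataFrame,
    model: ModelSpec,
    sire_of: dict,
    dam_of: dict,
) -> dict[str, np.ndarray]:
    """Method-of-moments estimates of all covariance blocks.

    Average outer products of weekly deviation vectors over five pair
    classes — the animal with itself, cage mates of a different / the
    same family, full sibs housed apart, and unrelated cage mates of
    those out-of-cage sibs — form a full-rank linear system in the
    unknown blocks (direct genetic, symmetrized direct-indirect,
    indirect genetic, group, permanent), because each class weights
    the blocks with different expected-relatedness coefficients.
    Occasional half-sib co-residents perturb the coefficients slightly;
    entirely adequate for REML starting values.
    """
    J = model.grid.J
    recs = records.sort_values(["animal", "week"], kind="stable")
    animals = recs["animal"].to_numpy()[::J]
    y = recs["adg"].to_numpy(dtype=float).reshape(-1, J)
    dev = y - y.mean(axis=0, keepdims=True)
    cage_series = records.drop_duplicates("animal").set_index("animal")["group"]
    cage_key = pd.factorize(cage_series.loc[animals].to_numpy())[0]
    fam_key = pd.factorize(
        pd.Series([(sire_of[a], dam_of[a]) for a in animals])
    )[0]
    sire_key = pd.factorize(pd.Series([sire_of[a] for a in animals]))[0]
    n = len(animals)
    n_cages = cage_key.max() + 1
    n_fams = fam_key.max() + 1

    cage_tot = np.zeros((n_cages, J))
    np.add.at(cage_tot, cage_key, dev)
    fam_tot = np.zeros((n_fams, J))
    np.add.at(fam_tot, fam_key, dev)
    fc_id = pd.factorize(cage_key.astype(np.int64) * n_fams + fam_key)[0]
    fc_tot = np.zeros((fc_id.max() + 1, J))
    np.add.at(fc_tot, fc_id, dev)
    # per-family sum over its cages of the non-family cage remainder
    fam_comp = np.zeros((n_fams, J))
    seen = set()
    for i in range(n):
        key = (fam_key[i], cage_key[i])
        if key in seen:
            continue
        seen.add(key)
        fam_comp[fam_key[i]] += cage_tot[cage_key[i]] - fc_tot[fc_id[i]]

    sib_in_cage = fc_tot[fc_id] - dev
    cage_diff_fam = cage_tot[cage_key] - fc_tot[fc_id]
    fam_out = fam_tot[fam_key] - fc_tot[fc_id]
    m6_partner = fam_comp[fam_key] - cage_diff_fam

    # paternal half sibs outside the own cage
    n_sires = sire_key.max() + 1
    sire_tot = np.zeros((n_sires, J))
    np.add.at(sire_tot, sire_key, dev)
    sc_id = pd.factorize(cage_key.astype(np.int64) * n_sires + sire_key)[0]
    sc_tot = np.zeros((sc_id.max() + 1, J))
    sc_cnt = np.zeros(sc_id.max() + 1)
    np.add.at(sc_tot, sc_id, dev)
    np.add.at(sc_cnt, sc_id, 1.0)
    fam_cnt = np.zeros(n_fams)
    np.add.at(fam_cnt, fam_key, 1.0)
    sire_cnt = np.zeros(n_sires)
    np.add.at(sire_cnt, sire_key, 1.0)
    # half sibs of i in its own cage: same (sire, cage), different dam
    fc_cnt = np.zeros(fc_tot.shape[0])
    np.add.at(fc_cnt, fc_id, 1.0)
    hs_out = (
        sire_tot[sire_key] - fam_tot[fam_key]
        - (sc_tot[sc_id] - fc_tot[fc_id])
    )
    hs_cnt = (
        sire_cnt[sire_key] - fam_cnt[fam_key]
        - (sc_cnt[sc_id] - fc_cnt[fc_id])
    )

    def sym(M):
        return (M + M.T) / 2.0

    M1 = sym(dev.T @ dev / n)
    M2 = sym(dev.T @ cage_diff_fam / (6.0 * n))
    M3 = sym(dev.T @ sib_in_cage / n)
    M4 = sym(dev.T @ fam_out / (6.0 * n))
    M5 = sym(dev.T @ hs_out / max(hs_cnt.sum(), 1.0))
    M6 = sym(dev.T @ m6_partner / (18.0 * n))

    stacked = np.stack([M1, M2, M3, M4, M5, M6])  # (6, J, J)
    x, *_ = np.linalg.lstsq(
        _MOMENT_COEFFS, stacked.reshape(6, -1), rcond=None
    )
    x = x.reshape(5, J, J)
    s_dd, s_sym, s_ii, s_g, s_p = (sym(m) for m in x)
    return {
        "dge": s_dd,
        "dge_ige": s_sym,
        "ige": s_ii,
        "group": s_g,
        "permanent": s_p,
    }


def moment_start(
    records: pd.DataFrame,
    model: ModelSpec,
    sire_of: dict,
    dam_of: dict,
) -> np.ndarray:
    """Starting parameter vector from the moment estimates, projected
    onto the model's SAD structure (PSD-floored first)."""
    from dataclasses import replace as _replace

    from .sad import project_sigma_to_cross_sad, project_sigma_to_sad

    est = moment_covariances(records, model, sire_of, dam_of)
    J = model.grid.J
    grid = model.grid
    s_g = _psd_floor(est["group"])
    s_p = _psd_floor(est["permanent"], rel=1e-2)
    gr_spec = model.group
    pm_spec = model.permanent
    group = project_sigma_to_sad(
        s_g, grid, gr_spec.order,
        tuple(f.degree for f in gr_spec.antedependence_fns),
        gr_spec.innovation_logvar_fn.degree,
    )
    permanent = project_sigma_to_sad(
        s_p, grid, pm_spec.order,
        tuple(f.degree for f in pm_spec.antedependence_fns),
        pm_spec.innovation_logvar_fn.degree,
    )
    if isinstance(model.genetic, CrossSADSpec):
        joint = np.block(
            [[est["dge"], est["dge_ige"]], [est["dge_ige"].T, est["ige"]]]
        )
        joint = _psd_floor(joint, rel=1e-3)
        gspec = model.genetic
        genetic = project_sigma_to_cross_sad(
            joint, grid,
            gspec.primary_spec.order, gspec.secondary_spec.order,
            tuple(f.degree for f in gspec.primary_spec.antedependence_fns),
            tuple(f.degree for f in gspec.secondary_spec.antedependence_fns),
            gspec.cross_fn.degree,
            gspec.primary_spec.innovation_logvar_fn.degree,
            gspec.secondary_spec.innovation_logvar_fn.degree,
        )
    else:
        # a model ignoring IGE: its group term absorbs the within-cage
        # covariance the indirect effects generate
        s_dd = _psd_floor(est["dge"])
        s_g_no = _psd_floor(
            est["group"] + 3.0 * est["dge_ige"] + 9.0 * est["ige"]
        )
        group = project_sigma_to_sad(
            s_g_no, grid, gr_spec.order,
            tuple(f.degree for f in gr_spec.antedependence_fns),
            gr_spec.innovation_logvar_fn.degree,
        )
        gspec = model.genetic
        genetic = project_sigma_to_sad(
            s_dd, grid, gspec.order,
            tuple(f.degree for f in gspec.antedependence_fns),
            gspec.innovation_logvar_fn.degree,
        )
    return _replace(
        model, genetic=genetic, group=group, permanent=permanent
    ).pack()
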
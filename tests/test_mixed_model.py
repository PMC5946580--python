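"""Residual-free SAD mixed model: design, REML likelihood (vs dense
oracle), fitting, BLUP (vs dense GLS) and likelihood-ratio tests."""

import numpy as np
import pandas as pd
import pytest

from conftest import founder_pedigree, toy_cage_records
from sadige.mixed_model import (
    FitResult,
    ModelSpec,
    build_design,
    compute_information,
    fit_reml,
    identifiability_diagnostics,
    lrt,
    predict_blup,
    reml_loglik,
)
from sadige.pedigree import Pedigree, build_A
from sadige.sad import (
    CrossSADSpec,
    PolyFn,
    SADSpec,
    TimeGrid,
    sigma_from_spec,
)


def small_model(grid, include_ige=True, litter=False):
    g1 = SADSpec((PolyFn((0.3,)),), PolyFn((0.5,)))
    if include_ige:
        genetic = CrossSADSpec(
            g1, SADSpec((PolyFn((0.2,)),), PolyFn((-1.0,))), PolyFn((-0.4,))
        )
    else:
        genetic = g1
    return ModelSpec(
        grid=grid,
        genetic=genetic,
        group=SADSpec((), PolyFn((0.8,))),
        permanent=SADSpec((PolyFn((0.1,)),), PolyFn((1.2,))),
        litter=SADSpec((), PolyFn((0.3,))) if litter else None,
    )


def dense_reml_oracle(y, X, V):
    """Textbook restricted likelihood from the dense marginal covariance."""
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    sld = np.linalg.slogdet
    n, p = X.shape
    return float(
        -0.5 * (sld(V)[1] + sld(XVX)[1] + y @ P @ y)
        - 0.5 * (n - p) * np.log(2 * np.pi)
    )


def dense_V(records, model, ped):
    """Independent construction of the marginal covariance of y."""
    recs = records.reset_index(drop=True)
    J = model.grid.J
    weeks = {w: j for j, w in enumerate(model.grid.weeks)}
    n = len(recs)
    covs = model.covariance_matrices()
    V = np.zeros((n, n))
    if model.genetic is not None:
        A = build_A(ped)
        Sge = covs["genetic"]
        gdim = Sge.shape[0]
        idx = {a: i for i, a in enumerate(ped.ids)}
        Z = np.zeros((n, ped.n * gdim))
        for r in range(n):
            a = idx[recs.animal[r]]
            w = weeks[float(recs.week[r])]
            Z[r, a * gdim + w] += 1
            if model.include_ige:
                mates = recs[
                    (recs.group == recs.group[r])
                    & (recs.week == recs.week[r])
                    & (recs.animal != recs.animal[r])
                ]
                for m in mates.animal:
                    Z[r, idx[m] * gdim + J + w] += 1
        V += Z @ np.kron(A, Sge) @ Z.T
    for r in range(n):
        for s in range(n):
            wr, ws = weeks[float(recs.week[r])], weeks[float(recs.week[s])]
            if model.group is not None and recs.group[r] == recs.group[s]:
                V[r, s] += covs["group"][wr, ws]
            if (
                model.litter is not None
                and recs.litter[r] == recs.litter[s]
            ):
                V[r, s] += covs["litter"][wr, ws]
            if recs.animal[r] == recs.animal[s]:
                V[r, s] += covs["permanent"][wr, ws]
    return V


@pytest.fixture
def toy24(grid3):
    """3 cages of 8 animals, 1-3 weeks, founder pedigree."""
    rng = np.random.default_rng(10)
    records = toy_cage_records(rng, n_cages=3, cage_size=8, weeks=(1, 2, 3))
    ped = founder_pedigree(sorted(records["animal"].unique()))
    return records, ped


class TestDesign:
    def test_ige_row_has_seven_mates(self, grid5):
        rng = np.random.default_rng(0)
        records = toy_cage_records(rng, n_cages=2, cage_size=8, weeks=(1,))
        model = small_model(TimeGrid((1,)))
        ped = founder_pedigree(sorted(records["animal"].unique()))
        design = build_design(records, model, ped)
        # each record row: 1 own DGE + 7 mate IGE entries
        row = design.Z[0].toarray().ravel()
        assert row.sum() == 1 + 7 + 1  # DGE + IGE + group

    def test_no_ige_columns_when_excluded(self):
        rng = np.random.default_rng(0)
        records = toy_cage_records(rng, n_cages=1, cage_size=4, weeks=(1,))
        grid = TimeGrid((1,))
        model = small_model(grid, include_ige=False)
        ped = founder_pedigree(sorted(records["animal"].unique()))
        design = build_design(records, model, ped)
        assert design.genetic_dim == 1

    def test_missing_week_drops_row_only(self, grid3):
        rng = np.random.default_rng(1)
        records = toy_cage_records(rng, n_cages=1, cage_size=4, weeks=(1, 2, 3))
        records = records[
            ~((records.animal == "a0") & (records.week == 2))
        ].reset_index(drop=True)
        model = small_model(grid3)
        ped = founder_pedigree(sorted(records["animal"].unique()))
        design = build_design(records, model, ped)
        assert design.n_records == 11
        # a0 has a 2-week pattern, others the full grid
        pats = {pat: idx.shape[0] for pat, idx in design.patterns}
        assert pats[(0, 2)] == 1 and pats[(0, 1, 2)] == 3

    def test_duplicate_record_rejected(self, grid3):
        rng = np.random.default_rng(2)
        records = toy_cage_records(rng, n_cages=1, cage_size=4, weeks=(1,))
        dup = pd.concat([records, records.iloc[[0]]], ignore_index=True)
        model = small_model(TimeGrid((1,)))
        ped = founder_pedigree(sorted(records["animal"].unique()))
        with pytest.raises(ValueError, match="duplicate"):
            build_design(dup, model, ped)

    def test_animal_missing_from_pedigree(self, grid3):
        rng = np.random.default_rng(3)
        records = toy_cage_records(rng, n_cages=1, cage_size=4, weeks=(1,))
        ped = founder_pedigree(["a0", "a1", "a2"])  # a3 missing
        with pytest.raises(KeyError, match="a3"):
            build_design(records, small_model(TimeGrid((1,))), ped)


class TestRemlLoglik:
    def test_matches_dense_oracle_toy(self, toy24, grid3):
        records, ped = toy24
        model = small_model(grid3)
        design = build_design(records, model, ped)
        omega = model.pack()
        ll = reml_loglik(omega, design, model)
        oracle = dense_reml_oracle(
            design.y, design.X, dense_V(records, model, ped)
        )
        assert abs(ll - oracle) < 1e-6

    def test_matches_dense_oracle_random_designs(self):
        """Property: MME likelihood equals the dense formula on small
        random designs (with litters, relatives, missing weeks)."""
        rng = np.random.default_rng(42)
        for k in range(8):
            n_cages = int(rng.integers(1, 3))
            cage = int(rng.choice([2, 4]))
            weeks = (1, 2) if rng.random() < 0.5 else (1, 2, 3)
            records = toy_cage_records(
                rng, n_cages=n_cages, cage_size=cage, weeks=weeks
            )
            # random litters; related animals via a parent generation
            animals = sorted(records["animal"].unique())
            records["litter"] = [
                f"L{hash(a) % 3}" for a in records["animal"]
            ]
            n_par = 4
            ids = [f"p{i}" for i in range(n_par)] + animals
            sire = [-1] * n_par + [
                int(rng.integers(0, 2)) for _ in animals
            ]
            dam = [-1] * n_par + [
                int(2 + rng.integers(0, 2)) for _ in animals
            ]
            ped = Pedigree(tuple(ids), np.array(sire), np.array(dam))
            if rng.random() < 0.3:  # random missing record
                records = records.iloc[1:].reset_index(drop=True)
            grid = TimeGrid(weeks)
            model = small_model(grid, include_ige=bool(rng.random() < 0.7),
                                litter=True)
            design = build_design(records, model, ped)
            omega = model.pack() + rng.uniform(-0.2, 0.2, model.n_params)
            ll = reml_loglik(omega, design, model)
            m2 = model.unpack(omega)
            oracle = dense_reml_oracle(
                design.y, design.X, dense_V(records, m2, ped)
            )
            assert abs(ll - oracle) < 1e-6

    def test_invariant_to_record_order(self, toy24, grid3):
        records, ped = toy24
        model = small_model(grid3)
        omega = model.pack()
        d1 = build_design(records, model, ped)
        shuffled = records.sample(frac=1.0, random_state=5)
        d2 = build_design(shuffled, model, ped)
        assert abs(
            reml_loglik(omega, d1, model) - reml_loglik(omega, d2, model)
        ) < 1e-8

    def test_translation_invariance(self, toy24, grid3):
        """Adding a constant to y leaves the restricted likelihood
        unchanged (week factors span the constant)."""
        records, ped = toy24
        model = small_model(grid3)
        omega = model.pack()
        d1 = build_design(records, model, ped)
        shifted = records.copy()
        shifted["adg"] = shifted["adg"] + 100.0
        d2 = build_design(shifted, model, ped)
        assert abs(
            reml_loglik(omega, d1, model) - reml_loglik(omega, d2, model)
        ) < 1e-7

    def test_nonfinite_on_bad_parameters(self, toy24, grid3):
        records, ped = toy24
        model = small_model(grid3)
        design = build_design(records, model, ped)
        omega = model.pack()
        omega[-1] = 1e4  # blows up the permanent innovation variance
        assert reml_loglik(omega, design, model) == -np.inf


class TestFitReml:
    def test_one_way_closed_form(self):
        """Balanced one-way layout (group + permanent, 1 week):
        REML equals the ANOVA estimator."""
        rng = np.random.default_rng(12)
        n_groups, k = 12, 8
        sig_g, sig_e = 4.0, 9.0
        rows = []
        for g in range(n_groups):
            ge = rng.normal(0, np.sqrt(sig_g))
            for i in range(k):
                rows.append(
                    {
                        "animal": f"g{g}i{i}",
                        "group": f"g{g}",
                        "week": 1,
                        "adg": 30 + ge + rng.normal(0, np.sqrt(sig_e)),
                    }
                )
        records = pd.DataFrame(rows)
        grid = TimeGrid((1,))
        model = ModelSpec(
            grid=grid,
            genetic=None,
            group=SADSpec((), PolyFn((0.0,))),
            permanent=SADSpec((), PolyFn((0.0,))),
        )
        fit = fit_reml(records, model, None, tol=1e-10)
        est = fit.covariance_matrices()
        # ANOVA REML for balanced one-way
        y = records["adg"].to_numpy().reshape(n_groups, k)
        msb = k * np.var(y.mean(axis=1), ddof=1)
        msw = np.mean(np.var(y, axis=1, ddof=1))
        assert abs(est["permanent"][0, 0] - msw) < 1e-4
        assert abs(est["group"][0, 0] - (msb - msw) / k) < 1e-4

    def test_refit_from_solution_is_fixed_point(self):
        rng = np.random.default_rng(13)
        records = toy_cage_records(rng, n_cages=4, cage_size=4, weeks=(1, 2))
        grid = TimeGrid((1, 2))
        model = ModelSpec(
            grid=grid,
            genetic=None,
            group=SADSpec((), PolyFn((0.0,))),
            permanent=SADSpec((PolyFn((0.0,)),), PolyFn((0.0,))),
        )
        fit = fit_reml(records, model, None, tol=1e-10)
        refit = fit_reml(records, model, None, init=fit.estimates, tol=1e-10)
        assert abs(refit.reml_loglik - fit.reml_loglik) < 1e-5


class TestLrt:
    def _fit_like(self, model, ll):
        return FitResult(
            model=model, estimates=model.pack(), reml_loglik=ll,
            converged=True, n_evaluations=0, trace=[],
        )

    def test_identical_models_zero(self, grid3):
        m = small_model(grid3)
        f = self._fit_like(m, -100.0)
        stat, df = lrt(f, f)
        assert stat == 0.0 and df == 0

    def test_statistic_and_df(self, grid3):
        full = small_model(grid3, include_ige=True)
        red = small_model(grid3, include_ige=False)
        f_full = self._fit_like(full, -95.0)
        f_red = self._fit_like(red, -100.0)
        stat, df = lrt(f_full, f_red)
        assert np.isclose(stat, 10.0)
        assert df == full.n_params - red.n_params

    def test_negative_statistic_raises(self, grid3):
        m = small_model(grid3)
        good = self._fit_like(m, -90.0)
        bad = self._fit_like(m, -80.0)
        with pytest.raises(ValueError, match="converge"):
            lrt(good, bad)


class TestBlup:
    def test_matches_dense_gls_toy(self, toy24, grid3):
        """MME solutions equal the closed-form GLS/BLUP expressions."""
        records, ped = toy24
        model = small_model(grid3)
        omega = model.pack()
        res = predict_blup(records, model, ped, omega)
        design = res.design
        V = dense_V(records, model, ped)
        X, y = design.X, design.y
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.allclose(res.fixed_effects.to_numpy(), beta, atol=1e-6)
        # genetic BLUP: u = G Z' V^-1 (y - X beta)
        covs = model.covariance_matrices()
        A = build_A(ped)
        Sge = covs["genetic"]
        gdim = Sge.shape[0]
        J = 3
        idx = {a: i for i, a in enumerate(ped.ids)}
        recs = records.reset_index(drop=True)
        Z = np.zeros((len(recs), ped.n * gdim))
        for r in range(len(recs)):
            a = idx[recs.animal[r]]
            w = int(recs.week[r]) - 1
            Z[r, a * gdim + w] += 1
            mates = recs[
                (recs.group == recs.group[r])
                & (recs.week == recs.week[r])
                & (recs.animal != recs.animal[r])
            ]
            for m_ in mates.animal:
                Z[r, idx[m_] * gdim + J + w] += 1
        u = np.kron(A, Sge) @ Z.T @ Vi @ (y - X @ beta)
        got = (
            res.ebv.sort_values(["animal", "week"])
            .loc[:, ["dge_ebv", "ige_ebv"]]
            .to_numpy()
        )
        want = u.reshape(ped.n, gdim)
        want = np.hstack([want[:, :J].reshape(-1, 1, 3),
                          want[:, J:].reshape(-1, 1, 3)])
        want = np.concatenate(
            [want[:, 0, :].reshape(-1, 1), want[:, 1, :].reshape(-1, 1)],
            axis=1,
        )
        assert np.allclose(got, want, atol=1e-6)

    def test_zero_phenotypic_deviation_gives_zero_ebv(self, grid3):
        rng = np.random.default_rng(20)
        records = toy_cage_records(rng, n_cages=2, cage_size=4, weeks=(1, 2, 3))
        records["adg"] = 0.0
        ped = founder_pedigree(sorted(records["animal"].unique()))
        model = small_model(grid3)
        res = predict_blup(records, model, ped, model.pack())
        assert np.allclose(res.ebv[["dge_ebv", "ige_ebv"]].to_numpy(), 0.0)

    def test_unphenotyped_relatives_receive_ebv(self, grid3):
        rng = np.random.default_rng(21)
        records = toy_cage_records(rng, n_cages=2, cage_size=4, weeks=(1, 2, 3))
        animals = sorted(records["animal"].unique())
        # two full-sib families -> the family contrast drives nonzero
        # parent EBVs (a single symmetric family would cancel exactly)
        ids = ["s", "d", "s2", "d2"] + animals
        half = len(animals) // 2
        ped = Pedigree(
            tuple(ids),
            np.array([-1, -1, -1, -1] + [0] * half + [2] * (len(animals) - half)),
            np.array([-1, -1, -1, -1] + [1] * half + [3] * (len(animals) - half)),
        )
        model = small_model(grid3)
        res = predict_blup(records, model, ped, model.pack())
        parent = res.ebv[res.ebv.animal == "s"]
        assert np.any(np.abs(parent["dge_ebv"]) > 1e-6)

    def test_mme_residual_identity(self, toy24, grid3):
        """Solutions satisfy C theta = rhs to 1e-8 (checked through an
        independent reconstruction of the equations)."""
        records, ped = toy24
        model = small_model(grid3)
        res = predict_blup(records, model, ped, model.pack())
        design = res.design
        from sadige.mixed_model import _build_Ginv, _build_Rinv
        from scipy import sparse as sp

        sigma_p = model.covariance_matrices()["permanent"]
        Rinv, _ = _build_Rinv(design, sigma_p)
        Ginv, _ = _build_Ginv(design, model)
        X = sp.csr_matrix(design.X)
        W = sp.hstack([X, design.Z], format="csr")
        C = W.T @ Rinv @ W + sp.block_diag(
            [sp.csc_matrix((design.n_fixed,) * 2), Ginv]
        )
        rhs = W.T @ (Rinv @ design.y)
        assert np.max(np.abs(C @ res.solution - rhs)) < 1e-8


class TestInformation:
    def test_condition_number_trivials(self, grid3):
        m = small_model(grid3)
        fit = FitResult(
            model=m, estimates=m.pack(), reml_loglik=0.0, converged=True,
            n_evaluations=0, trace=[], info_matrix=np.eye(4),
        )
        assert identifiability_diagnostics(fit)["condition_number"] == 1.0
        fit.info_matrix = np.diag([4.0, 1.0])
        assert np.isclose(
            identifiability_diagnostics(fit)["condition_number"], 2.0
        )

    def test_information_positive_definite_at_optimum(self):
        rng = np.random.default_rng(30)
        records = toy_cage_records(rng, n_cages=6, cage_size=4, weeks=(1,))
        # inject a real group effect so its variance is interior
        g_eff = {g: rng.normal(0, 3.0) for g in records["group"].unique()}
        records["adg"] += records["group"].map(g_eff)
        grid = TimeGrid((1,))
        model = ModelSpec(
            grid=grid, genetic=None,
            group=SADSpec((), PolyFn((0.0,))),
            permanent=SADSpec((), PolyFn((0.0,))),
        )
        fit = fit_reml(records, model, None, tol=1e-10)
        design = build_design(records, model, None)
        info = compute_information(design, model, fit.estimates)
        assert np.all(np.linalg.eigvalsh(info) > 0)
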
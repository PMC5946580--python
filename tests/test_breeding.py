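"""Closed-nucleus selection simulator: population construction, group
assignment, phenotype generation, selection rules and recovery metrics."""

import numpy as np
import pandas as pd
import pytest

from dataclasses import replace

from sadige import breeding as br
from sadige.mixed_model import FitResult
from sadige.sad import project_sigma_to_cross_sad, project_sigma_to_sad


SMALL = br.SimulationConfig(n_sires=8, n_dams=16, dams_per_sire=2,
                            n_generations=2)


def zero_params(antagonism="strong"):
    return br.GeneticParameters(
        sigma_ge=np.zeros((10, 10)),
        sigma_group=np.zeros((5, 5)),
        sigma_perm=np.zeros((5, 5)),
        week_means=np.array([26.5, 37.5, 42.0, 40.1, 41.2]),
        antagonism=antagonism,
    )


def truth_projection_fit(params, include_ige=True):
    """FitResult at the SAD projection of the true covariances (an
    oracle for pipeline tests that bypasses REML)."""
    model = br.default_model_spec(include_ige=include_ige)
    gr = project_sigma_to_sad(params.sigma_group, model.grid, 1, (1,), 1)
    pm = project_sigma_to_sad(params.sigma_perm, model.grid, 1, (1,), 1)
    if include_ige:
        g = project_sigma_to_cross_sad(
            params.sigma_ge, model.grid, 1, 1, (1,), (1,), 1, 1, 1
        )
    else:
        g = project_sigma_to_sad(params.sigma_ge[:5, :5], model.grid, 1, (1,), 1)
    m = replace(model, genetic=g, group=gr, permanent=pm)
    return model, FitResult(
        model=model, estimates=m.pack(), reml_loglik=0.0, converged=True,
        n_evaluations=0, trace=[],
    )


class TestGeneticParameters:
    def test_default_levels_scale_only_cross_block(self):
        strong = br.GeneticParameters.default("strong")
        weak = br.GeneticParameters.default("weak")
        assert np.allclose(
            strong.sigma_ge[:5, :5], weak.sigma_ge[:5, :5]
        )
        assert np.allclose(
            strong.sigma_ge[:5, 5:], 4.0 * weak.sigma_ge[:5, 5:]
        )
        assert np.allclose(strong.sigma_group, weak.sigma_group)

    def test_all_levels_psd(self):
        for level in ("strong", "moderate", "weak"):
            p = br.GeneticParameters.default(level)
            assert np.linalg.eigvalsh(p.sigma_ge)[0] > -1e-10

    def test_non_psd_rejected(self):
        bad = -np.eye(10)
        with pytest.raises(ValueError, match="positive semi-definite"):
            br.GeneticParameters(
                sigma_ge=bad, sigma_group=np.eye(5), sigma_perm=np.eye(5),
                week_means=np.zeros(5),
            )


class TestFounders:
    def test_counts_and_sexes(self):
        params = br.GeneticParameters.default()
        pop, sires, dams = br.simulate_founders(
            params, br.SimulationConfig(), seed=1
        )
        assert len(sires) == 30 and len(dams) == 120
        assert all(pop.sex_male[s] for s in sires)
        assert not any(pop.sex_male[d] for d in dams)

    def test_zero_genetic_variance_gives_zero_bv(self):
        pop, _, _ = br.simulate_founders(zero_params(), SMALL, seed=2)
        assert np.allclose(pop.bv, 0.0)

    def test_founder_bv_covariance(self):
        params = br.GeneticParameters.default()
        big = br.SimulationConfig(n_sires=4000, n_dams=16000,
                                  dams_per_sire=4)
        pop, _, _ = br.simulate_founders(params, big, seed=3)
        emp = np.cov(pop.bv, rowvar=False)
        S = params.sigma_ge
        n = pop.n
        se = np.sqrt((np.outer(np.diag(S), np.diag(S)) + S**2) / n)
        assert np.all(np.abs(emp - S) < 4 * se + 1e-12)


class TestMateAndDrop:
    def test_zero_everything_zero_offspring(self):
        pop, sires, dams = br.simulate_founders(zero_params(), SMALL, 4)
        matings = [(int(sires[0]), int(dams[0]))]
        off = br.mate_and_drop(pop, matings, zero_params(), SMALL, 0, 5)
        assert np.allclose(pop.bv[off], 0.0)

    def test_cohort_size(self):
        params = br.GeneticParameters.default()
        cfg = br.SimulationConfig()
        pop, cohort, records, matings = br.simulate_base_generation(
            params, cfg, 6
        )
        assert len(cohort) == 960
        assert len(matings) == 120
        assert len(records) == 4800

    def test_mendelian_within_family_covariance(self):
        """Offspring deviations from the parent average have
        covariance half the genetic matrix."""
        params = br.GeneticParameters.default()
        cfg = br.SimulationConfig(
            n_sires=1, n_dams=4, dams_per_sire=4,
            offspring_per_mating=5000, families_per_group=4,
            per_family_per_group=2, group_size=8,
        )
        pop, sires, dams = br.simulate_founders(params, cfg, 7)
        matings = [(int(sires[0]), int(d)) for d in dams]
        off = br.mate_and_drop(pop, matings, params, cfg, 0, 8)
        bv = pop.bv
        devs = []
        for k, (s, d) in enumerate(matings):
            fam = off[k * 5000 : (k + 1) * 5000]
            devs.append(bv[fam] - 0.5 * (bv[s] + bv[d]))
        devs = np.vstack(devs)
        emp = np.cov(devs, rowvar=False)
        S = 0.5 * params.sigma_ge
        se = np.sqrt((np.outer(np.diag(S), np.diag(S)) + S**2) / len(devs))
        assert np.all(np.abs(emp - S) < 4 * se + 1e-12)


class TestGroupAssignment:
    def test_partition_structure(self):
        params = br.GeneticParameters.default()
        cfg = br.SimulationConfig()
        pop, cohort, _, _ = br.simulate_base_generation(params, cfg, 9)
        groups = br.assign_groups(pop, cohort, cfg, seed=10)
        assert groups.min() == 0 and groups.max() == 119
        fam = np.asarray([pop.sire[i] * 1000 + pop.dam[i] for i in cohort])
        for g in range(120):
            members = np.flatnonzero(groups == g)
            assert len(members) == 8
            counts = pd.Series(fam[members]).value_counts()
            assert sorted(counts) == [2, 2, 2, 2]

    def test_every_animal_exactly_once(self):
        params = br.GeneticParameters.default()
        pop, cohort, _, _ = br.simulate_base_generation(params, SMALL, 11)
        groups = br.assign_groups(pop, cohort, SMALL, seed=12)
        assert np.all(groups >= 0)
        assert len(groups) == len(cohort)

    def test_seed_determinism(self):
        params = br.GeneticParameters.default()
        pop, cohort, _, _ = br.simulate_base_generation(params, SMALL, 13)
        a = br.assign_groups(pop, cohort, SMALL, seed=14)
        b = br.assign_groups(pop, cohort, SMALL, seed=14)
        assert np.array_equal(a, b)


class TestPhenotypes:
    def test_all_variances_zero_gives_week_means(self):
        params = zero_params()
        pop, cohort, records, _ = br.simulate_base_generation(
            params, SMALL, 15
        )
        by_week = records.groupby("week")["adg"].agg(["min", "max"])
        for j, mu in enumerate(params.week_means, start=1):
            assert np.allclose(by_week.loc[j], mu)

    def test_ige_incidence_structure(self):
        """Perturbing one animal's IGE changes exactly its 7 cage
        mates' phenotypes, not its own."""
        params = br.GeneticParameters.default()
        cfg = SMALL
        pop, cohort, _, _ = br.simulate_base_generation(params, cfg, 16)
        groups = br.assign_groups(pop, cohort, cfg, seed=17)
        r1 = br.generate_phenotypes(pop, cohort, groups, params, cfg, 18)
        victim = cohort[0]
        pop.bv_rows[victim] = pop.bv_rows[victim] + np.concatenate(
            [np.zeros(5), np.ones(5)]
        )
        r2 = br.generate_phenotypes(pop, cohort, groups, params, cfg, 18)
        diff = (r2["adg"] - r1["adg"]).abs() > 1e-12
        changed = set(r2.loc[diff, "animal"])
        mates = set(
            cohort[np.flatnonzero(groups == groups[0])]
        ) - {victim}
        assert changed == mates

    def test_phenotypic_variance_matches_partition(self):
        """Empirical weekly variance agrees with the analytic total
        (no litter, r from the simulated pedigree)."""
        from sadige.pedigree import build_A, mean_cage_relatedness
        from sadige.summaries import (
            VariancePartition,
            total_phenotypic_variance,
        )

        params = br.GeneticParameters.default()
        cfg = br.SimulationConfig()
        reps = []
        for s in range(8):
            pop, cohort, records, _ = br.simulate_base_generation(
                params, cfg, 600 + s
            )
            reps.append(records.groupby("week")["adg"].var(ddof=1))
        emp = np.mean(reps, axis=0)
        pop, cohort, records, _ = br.simulate_base_generation(
            params, cfg, 600
        )
        A = build_A(pop.pedigree())
        groups = {
            g: sub["animal"].unique()
            for g, sub in records.groupby("group")
        }
        r = mean_cage_relatedness(A, groups)
        part = VariancePartition(
            dge=np.diag(params.sigma_ge)[:5],
            ige=np.diag(params.sigma_ge)[5:],
            dge_ige=np.diag(params.sigma_ge[:5, 5:]),
            litter=np.zeros(5),
            group=np.diag(params.sigma_group),
            permanent=np.diag(params.sigma_perm),
            n_group=8,
            relatedness=r,
        )
        want = total_phenotypic_variance(part)
        # cross-module consistency within Monte-Carlo tolerance
        assert np.all(np.abs(emp - want) / want < 0.10)


class TestTebv:
    @pytest.mark.parametrize(
        "direct, indirect, size, expected",
        [(1.0, 0.5, 8, 4.5), (2.0, 0.0, 8, 2.0), (1.0, 1.0, 2, 2.0)],
    )
    def test_values(self, direct, indirect, size, expected):
        got = br.compute_tebv(
            np.array([direct]), np.array([indirect]), group_size=size
        )
        assert np.isclose(got[0], expected)


class TestSelection:
    def _cohort(self, seed=19):
        params = br.GeneticParameters.default()
        pop, cohort, _, _ = br.simulate_base_generation(params, SMALL, seed)
        return pop, cohort

    def test_one_male_per_sire_family_is_family_max(self):
        pop, cohort = self._cohort()
        rng = np.random.default_rng(20)
        crit = rng.normal(size=len(cohort))
        males, females, matings = br.select_breeders(
            pop, cohort, crit, SMALL, seed=21
        )
        sire_of = np.asarray([pop.sire[i] for i in cohort])
        male_mask = np.asarray([pop.sex_male[i] for i in cohort])
        assert len(males) == SMALL.n_sires
        for m in males:
            fam = pop.sire[m]
            cand = np.flatnonzero((sire_of == fam) & male_mask)
            best = cand[np.argmax(crit[cand])]
            assert crit[np.flatnonzero(cohort == m)[0]] == crit[best]

    def test_female_truncation_count(self):
        pop, cohort = self._cohort()
        crit = np.arange(len(cohort), dtype=float)
        males, females, _ = br.select_breeders(
            pop, cohort, crit, SMALL, seed=22
        )
        assert len(females) == SMALL.n_dams

    def test_tie_break_lowest_id(self):
        pop, cohort = self._cohort()
        crit = np.zeros(len(cohort))
        males, females, _ = br.select_breeders(
            pop, cohort, crit, SMALL, seed=23
        )
        # within each sire family the chosen male is the lowest-id male
        sire_of = np.asarray([pop.sire[i] for i in cohort])
        male_mask = np.asarray([pop.sex_male[i] for i in cohort])
        for m in males:
            fam_males = cohort[(sire_of == pop.sire[m]) & male_mask]
            assert m == fam_males.min()

    def test_no_mating_within_sire_family(self):
        pop, cohort = self._cohort()
        rng = np.random.default_rng(24)
        crit = rng.normal(size=len(cohort))
        _, _, matings = br.select_breeders(pop, cohort, crit, SMALL, seed=25)
        assert len(matings) == SMALL.n_dams
        for s, d in matings:
            assert pop.sire[s] != pop.sire[d]
        # each sire serves exactly dams_per_sire dams
        counts = pd.Series([s for s, _ in matings]).value_counts()
        assert (counts == SMALL.dams_per_sire).all()


class TestRecoveryMetrics:
    def test_oracle_fitter_zero_bias(self):
        """A fitter returning the truth gives exactly zero bias and
        dispersion — pipeline plumbing check."""
        params = br.GeneticParameters.default()

        def oracle(records, ped, model):
            return {
                "genetic": params.sigma_ge.copy(),
                "group": params.sigma_group.copy(),
                "permanent": params.sigma_perm.copy(),
            }, True

        table, meta = br.recovery_study(
            params, SMALL, replicates=3, seed=1, fitter=oracle
        )
        assert meta["pct_used"] == 100.0
        assert np.allclose(table["average"], 0.0, atol=1e-12)
        assert np.allclose(table["max"], 0.0, atol=1e-12)

    def test_bias_and_cv_definitions(self):
        """Hand-computed 3-replicate toy validates the metric
        arithmetic: relative bias (E(est)-true)/true*100 and
        CV sd/mean*100 for variances; plain bias and SD for
        correlations."""
        params = br.GeneticParameters.default()
        truth_d = np.diag(params.sigma_ge)[:5]
        fakes = [0.9, 1.0, 1.4]  # scale factors per replicate

        calls = {"i": 0}

        def fitter(records, ped, model):
            f = fakes[calls["i"]]
            calls["i"] += 1
            return {
                "genetic": params.sigma_ge * f,
                "group": params.sigma_group * f,
                "permanent": params.sigma_perm,
            }, True

        table, _ = br.recovery_study(
            params, SMALL, replicates=3, seed=2, fitter=fitter
        )
        row = table[
            (table.component == "direct_genetic_variance")
            & (table.criterion == "relative_bias_pct")
        ].iloc[0]
        want_bias = (np.mean(fakes) - 1.0) * 100.0
        assert np.isclose(row["average"], want_bias)
        row_cv = table[
            (table.component == "direct_genetic_variance")
            & (table.criterion == "cv_pct")
        ].iloc[0]
        want_cv = np.std(fakes, ddof=1) / np.mean(fakes) * 100.0
        assert np.isclose(row_cv["average"], want_cv)
        # scaling the whole matrix leaves correlations untouched
        row_corr = table[
            (table.component == "direct_genetic_correlation")
            & (table.criterion == "bias")
        ].iloc[0]
        assert np.isclose(row_corr["average"], 0.0, atol=1e-12)

    def test_nonconverged_replicates_excluded(self):
        params = br.GeneticParameters.default()
        calls = {"i": 0}

        def flaky(records, ped, model):
            calls["i"] += 1
            ok = calls["i"] % 2 == 1
            return {
                "genetic": params.sigma_ge,
                "group": params.sigma_group,
                "permanent": params.sigma_perm,
            }, ok

        table, meta = br.recovery_study(
            params, SMALL, replicates=4, seed=3, fitter=flaky
        )
        assert meta["converged"] == 2
        assert meta["pct_used"] == 50.0


class TestScenario:
    def test_zero_heritable_variance_flat_response(self):
        """No genetic variance: selection cannot move the mean."""
        params = zero_params()
        model, fit = truth_projection_fit(
            br.GeneticParameters.default(), include_ige=True
        )
        # variance components don't matter for the *true* response here
        res = br.run_scenario(
            params, SMALL, scenario=3, seed=31, fit=fit, model=model
        )
        assert np.allclose(res.mean_adg, res.mean_adg[0], atol=1e-9)

    def test_selection_moves_mean_with_heritable_variance(self):
        params = br.GeneticParameters.default("weak")
        model, fit = truth_projection_fit(params, include_ige=True)
        cfg = replace(SMALL, n_generations=3)
        res = br.run_scenario(
            params, cfg, scenario=3, seed=32, fit=fit, model=model
        )
        assert res.mean_adg[-1] > res.mean_adg[0]

    def test_random_criterion_no_systematic_response(self):
        """Selection on pure noise leaves expected response at zero."""
        params = br.GeneticParameters.default("weak")
        model, fit = truth_projection_fit(params)
        cfg = replace(SMALL, n_generations=2)
        res = []
        for rep in range(10):
            base = br.simulate_base_generation(params, cfg, 300 + rep)
            out = br.run_scenario(
                params, cfg, scenario=3, seed=300 + rep, fit=fit,
                base=base, model=model, criterion_override="random",
            )
            res.append(out.mean_adg[-1] - out.mean_adg[0])
        lo = np.mean(res) - 3 * np.std(res, ddof=1) / np.sqrt(len(res))
        hi = np.mean(res) + 3 * np.std(res, ddof=1) / np.sqrt(len(res))
        assert lo < 0.0 < hi
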
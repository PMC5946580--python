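"""Closed-nucleus selection simulation for a group-housed trait with IGE.

The simulated breeding program mirrors a standard rabbit nucleus:
30 unrelated sires x 120 unrelated dams, 8 offspring per mating
(balanced sexes), cohorts of 960 housed in cages of eight composed of
four full-sib families contributing two kits each.  Weekly phenotypes
follow the IGE model without a litter term::

    y_im(w_j) = mu(w_j) + DGE_i(w_j) + sum_mates IGE_k(w_j)
                + g_m(w_j) + p_i(w_j)

True breeding values are simulated from *unstructured* multivariate
normal covariances while genetic evaluation fits SAD structures — the
deliberate mild misspecification of the original design is preserved.

Selection runs for seven discrete generations: the best male per sire
family and the best 120 females are kept, and each selected male is
mated to four selected females avoiding matings within a sire family.
Three selection criteria are compared: the summed weekly direct EBVs
from a model ignoring IGE (scenario 1), the week-1 total EBV (TEBV =
direct + 7 x indirect) from the full model (scenario 2), and the summed
weekly TEBVs (scenario 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import params as default_params
from .mixed_model import FitResult, ModelSpec, predict_blup
from .pedigree import Pedigree
from .sad import CrossSADSpec, PolyFn, SADSpec, TimeGrid, default_grid

#: REML protocol for base-cohort fits: ladder start, restart-stabilized
#: L-BFGS-B; a replicate counts as converged when a restart gains less
#: than REML_RESTART_TOL log-likelihood units before the restart budget
#: is exhausted and no variance collapses to the parameter boundary
REML_RESTARTS = 4
REML_RESTART_TOL = 0.25
REML_MAX_EVALUATIONS = 400

__all__ = [
    "GeneticParameters",
    "SimulationConfig",
    "ScenarioResult",
    "Population",
    "simulate_founders",
    "mate_and_drop",
    "assign_groups",
    "generate_phenotypes",
    "compute_tebv",
    "select_breeders",
    "run_scenario",
    "recovery_study",
    "default_model_spec",
    "sad1_11_cross_template",
    "sad1_11_single_template",
]

_ANTAGONISM_DIVISOR = {"strong": 1.0, "moderate": 2.0, "weak": 4.0}


def _mvn(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    """MVN(0, cov) draws via the eigendecomposition (PSD-safe)."""
    w, V = np.linalg.eigh((cov + cov.T) / 2.0)
    root = V * np.sqrt(np.maximum(w, 0.0))
    return rng.standard_normal((size, cov.shape[0])) @ root.T


@dataclass(frozen=True)
class GeneticParameters:
    """Unstructured simulation truth for all random effects."""

    sigma_ge: np.ndarray        # 10x10, [DGE w1-5, IGE w1-5]
    sigma_group: np.ndarray     # 5x5
    sigma_perm: np.ndarray      # 5x5
    week_means: np.ndarray      # length 5
    antagonism: str = "strong"

    def __post_init__(self) -> None:
        for name in ("sigma_ge", "sigma_group", "sigma_perm"):
            M = np.asarray(getattr(self, name), dtype=float)
            ev = np.linalg.eigvalsh((M + M.T) / 2.0)
            if ev[0] < -1e-8 * max(np.trace(M), 1.0):
                raise ValueError(f"{name} is not positive semi-definite")
            object.__setattr__(self, name, M)
        object.__setattr__(
            self, "week_means", np.asarray(self.week_means, dtype=float)
        )

    @staticmethod
    def default(antagonism: str = "strong") -> "GeneticParameters":
        """Bundled parameter set at the requested antagonism level.

        ``strong`` keeps the full negative direct-indirect covariance;
        ``moderate`` and ``weak`` divide the cross block by 2 and 4.
        """
        div = _ANTAGONISM_DIVISOR[antagonism]
        sigma_ge = default_params.scale_cross_block(
            default_params.default_genetic_covariance(), div
        )
        return GeneticParameters(
            sigma_ge=sigma_ge,
            sigma_group=default_params.default_group_covariance(),
            sigma_perm=default_params.default_permanent_covariance(),
            week_means=default_params.WEEK_MEANS.copy(),
            antagonism=antagonism,
        )

    @property
    def n_weeks(self) -> int:
        return self.week_means.size


@dataclass(frozen=True)
class SimulationConfig:
    n_sires: int = 30
    n_dams: int = 120
    dams_per_sire: int = 4
    offspring_per_mating: int = 8
    n_generations: int = 7
    group_size: int = 8
    families_per_group: int = 4
    per_family_per_group: int = 2
    evaluation_window: str = "current"   # or "cumulative"

    def __post_init__(self) -> None:
        if self.n_sires * self.dams_per_sire != self.n_dams:
            raise ValueError("n_dams must equal n_sires * dams_per_sire")
        if self.families_per_group * self.per_family_per_group != self.group_size:
            raise ValueError("group composition inconsistent with group size")
        if self.offspring_per_mating % self.per_family_per_group:
            raise ValueError(
                "offspring_per_mating must be divisible by per_family_per_group"
            )
        if self.cohort_size % self.group_size:
            raise ValueError("cohort size must be divisible by group size")

    @property
    def cohort_size(self) -> int:
        return self.n_dams * self.offspring_per_mating


@dataclass
class Population:
    """Growing pedigree with true breeding-value trajectories.

    Rows are pedigree-ordered; ``bv`` holds [DGE w1-5, IGE w1-5] per
    animal.  ``generation`` is 0 for the current cohort's founders etc.
    """

    sire: list[int] = field(default_factory=list)
    dam: list[int] = field(default_factory=list)
    sex_male: list[bool] = field(default_factory=list)
    generation: list[int] = field(default_factory=list)
    bv_rows: list[np.ndarray] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.sire)

    @property
    def bv(self) -> np.ndarray:
        return np.vstack(self.bv_rows) if self.bv_rows else np.zeros((0, 0))

    def add(self, sire: int, dam: int, male: bool, gen: int, bv: np.ndarray) -> int:
        self.sire.append(sire)
        self.dam.append(dam)
        self.sex_male.append(male)
        self.generation.append(gen)
        self.bv_rows.append(bv)
        return self.n - 1

    def pedigree(self) -> Pedigree:
        n = self.n
        return Pedigree(
            tuple(range(n)),
            np.asarray(self.sire, dtype=np.int64),
            np.asarray(self.dam, dtype=np.int64),
        )

    def cohort(self, gen: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.generation) == gen)


def simulate_founders(
    params: GeneticParameters, config: SimulationConfig, seed
) -> tuple[Population, np.ndarray, np.ndarray]:
    """Unrelated founders with MVN breeding values; returns the
    population and the (sires, dams) index arrays."""
    rng = np.random.default_rng(seed)
    pop = Population()
    n_f = config.n_sires + config.n_dams
    bvs = _mvn(rng, params.sigma_ge, n_f)
    sires = []
    dams = []
    for i in range(config.n_sires):
        sires.append(pop.add(-1, -1, True, -1, bvs[i]))
    for i in range(config.n_dams):
        dams.append(pop.add(-1, -1, False, -1, bvs[config.n_sires + i]))
    return pop, np.asarray(sires), np.asarray(dams)


def mate_and_drop(
    pop: Population,
    matings: list[tuple[int, int]],
    params: GeneticParameters,
    config: SimulationConfig,
    gen: int,
    seed,
) -> np.ndarray:
    """Produce offspring: parent-average BV plus Mendelian sampling.

    The Mendelian deviation is MVN with covariance half the genetic
    matrix (founder parents are non-inbred at every generation of this
    short program, so the 1/2 scalar is used throughout; inbreeding of
    later cohorts is ignored here as in the original design).  Sexes
    are balanced within each litter.
    """
    rng = np.random.default_rng(seed)
    k = config.offspring_per_mating
    n_off = len(matings) * k
    mend = _mvn(rng, 0.5 * params.sigma_ge, n_off)
    offspring = []
    bv_arr = pop.bv
    pos = 0
    for s, d in matings:
        mid = 0.5 * (bv_arr[s] + bv_arr[d])
        sexes = np.array([True] * (k // 2) + [False] * (k - k // 2))
        rng.shuffle(sexes)
        for j in range(k):
            offspring.append(
                pop.add(s, d, bool(sexes[j]), gen, mid + mend[pos])
            )
            pos += 1
    return np.asarray(offspring)


def assign_groups(
    pop: Population, cohort: np.ndarray, config: SimulationConfig, seed
) -> np.ndarray:
    """Cage assignment: chunks of ``families_per_group`` full-sib
    families, each family contributing ``per_family_per_group`` kits to
    each cage of the chunk.  Returns a group id per cohort member."""
    rng = np.random.default_rng(seed)
    fam_key = np.asarray(
        [pop.sire[i] * 100000 + pop.dam[i] for i in cohort]
    )
    families = pd.unique(fam_key)
    n_per_chunk = config.families_per_group
    if len(families) % n_per_chunk:
        raise ValueError("family count not divisible by families per group")
    perm = rng.permutation(len(families))
    cages_per_chunk = (
        n_per_chunk * config.offspring_per_mating // config.group_size
    )
    group_of = np.full(len(cohort), -1, dtype=np.int64)
    gid = 0
    for c in range(len(families) // n_per_chunk):
        fam_chunk = families[perm[c * n_per_chunk : (c + 1) * n_per_chunk]]
        for fam in fam_chunk:
            members = np.flatnonzero(fam_key == fam)
            members = rng.permutation(members)
            for cage in range(cages_per_chunk):
                sel = members[
                    cage * config.per_family_per_group :
                    (cage + 1) * config.per_family_per_group
                ]
                group_of[sel] = gid + cage
        gid += cages_per_chunk
    if np.any(group_of < 0):
        raise ValueError("infeasible cage assignment")
    return group_of


def generate_phenotypes(
    pop: Population,
    cohort: np.ndarray,
    groups: np.ndarray,
    params: GeneticParameters,
    config: SimulationConfig,
    seed,
    group_id_offset: int = 0,
) -> pd.DataFrame:
    """Weekly phenotypes for one cohort (long format, one row per
    animal-week): week mean + own DGE + mates' IGE + group + permanent."""
    rng = np.random.default_rng(seed)
    J = params.n_weeks
    n = len(cohort)
    bv = pop.bv[cohort]
    dge = bv[:, :J]
    ige = bv[:, J:]
    n_groups = groups.max() + 1
    g_eff = _mvn(rng, params.sigma_group, n_groups)
    p_eff = _mvn(rng, params.sigma_perm, n)
    # mates' IGE sums: per group total minus own contribution
    ige_sum = np.zeros((n, J))
    for g in range(n_groups):
        members = np.flatnonzero(groups == g)
        tot = ige[members].sum(axis=0)
        ige_sum[members] = tot - ige[members]
    y = (
        params.week_means[None, :]
        + dge
        + ige_sum
        + g_eff[groups]
        + p_eff
    )
    return pd.DataFrame(
        {
            "animal": np.repeat(cohort, J),
            "group": np.repeat(groups + group_id_offset, J),
            "week": np.tile(np.arange(1, J + 1), n),
            "adg": y.ravel(),
        }
    )


def compute_tebv(
    ebv_direct: np.ndarray, ebv_indirect: np.ndarray, group_size: int = 8
) -> np.ndarray:
    """Total EBV per week: direct + (group size - 1) x indirect."""
    return np.asarray(ebv_direct) + (group_size - 1) * np.asarray(ebv_indirect)


def select_breeders(
    pop: Population,
    cohort: np.ndarray,
    criterion: np.ndarray,
    config: SimulationConfig,
    seed,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Within-family male selection, across-family female truncation,
    and random mating avoiding sire-family matings.

    Returns (selected males, selected females, matings).  Ties are
    broken by lowest animal id.
    """
    rng = np.random.default_rng(seed)
    sire_of = np.asarray([pop.sire[i] for i in cohort])
    male = np.asarray([pop.sex_male[i] for i in cohort])

    # best male per sire family (stable: ties go to the lowest id)
    chosen_males = []
    for fam in np.unique(sire_of):
        cand = np.flatnonzero((sire_of == fam) & male)
        if len(cand) == 0:
            raise ValueError(f"sire family {fam} has no male candidate")
        best = cand[np.lexsort((cohort[cand], -criterion[cand]))[0]]
        chosen_males.append(best)
    chosen_males = np.asarray(chosen_males)

    females = np.flatnonzero(~male)
    if len(females) < config.n_dams:
        raise ValueError("not enough female candidates")
    order = np.lexsort((cohort[females], -criterion[females]))
    chosen_females = females[order[: config.n_dams]]

    males_idx = cohort[chosen_males]
    females_idx = cohort[chosen_females]
    matings = _assign_matings(pop, males_idx, females_idx, config, rng)
    return males_idx, females_idx, matings


def _assign_matings(
    pop: Population,
    males: np.ndarray,
    females: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Random 1 sire : ``dams_per_sire`` dams, no shared sire family."""
    male_fam = np.asarray([pop.sire[i] for i in males])
    female_fam = np.asarray([pop.sire[i] for i in females])
    for _ in range(200):
        perm = rng.permutation(len(females))
        slots: list[list[int]] = [[] for _ in males]
        ok = True
        fill = list(perm)
        leftovers: list[int] = []
        m = 0
        for f in fill:
            placed = False
            for attempt in range(len(males)):
                cand = (m + attempt) % len(males)
                if (
                    len(slots[cand]) < config.dams_per_sire
                    and male_fam[cand] != female_fam[f]
                ):
                    slots[cand].append(f)
                    m = (cand + 1) % len(males)
                    placed = True
                    break
            if not placed:
                leftovers.append(f)
        if not leftovers and all(
            len(s) == config.dams_per_sire for s in slots
        ):
            return [
                (int(males[i]), int(females[f]))
                for i, s in enumerate(slots)
                for f in s
            ]
    raise ValueError("could not build a mating plan without sire-family overlap")


@dataclass
class ScenarioResult:
    scenario: int
    antagonism: str
    mean_adg: np.ndarray          # per generation (0..n_generations)
    weekly_mean: np.ndarray       # (n_generations+1, J)
    fit: FitResult | None = None
    converged: bool = True


# ---------------------------------------------------------------------------
# model templates (the structures selected for this design)


def sad1_11_single_template(grid: TimeGrid) -> SADSpec:
    """SAD1-11: order-1 antedependence, degree-1 theta and log-variance."""
    return SADSpec(
        (PolyFn((0.0, 0.0)),), PolyFn((0.0, 0.0))
    )


def sad1_11_cross_template(grid: TimeGrid) -> CrossSADSpec:
    """Correlated DGE/IGE, SAD1-11 each, degree-1 cross-antedependence."""
    return CrossSADSpec(
        sad1_11_single_template(grid),
        sad1_11_single_template(grid),
        PolyFn((0.0, 0.0)),
    )


def default_model_spec(
    grid: TimeGrid | None = None, include_ige: bool = True,
    include_litter: bool = False,
) -> ModelSpec:
    """The evaluation model for the nucleus design: SAD1-11 for every
    random-effect function, degree-1 cross term when IGE are included.

    The default grid centres the week index (polynomials in ``w - 3``),
    which spans the same model space as raw-week polynomials but keeps
    the intercept/slope coefficients of each polynomial nearly
    orthogonal — materially better REML convergence.
    """
    grid = grid or TimeGrid((1, 2, 3, 4, 5), shift=3.0)
    genetic = (
        sad1_11_cross_template(grid) if include_ige
        else sad1_11_single_template(grid)
    )
    return ModelSpec(
        grid=grid,
        genetic=genetic,
        group=sad1_11_single_template(grid),
        permanent=sad1_11_single_template(grid),
        litter=sad1_11_single_template(grid) if include_litter else None,
    )


def fit_base_cohort(
    records: pd.DataFrame,
    pop: Population,
    cohort: np.ndarray,
    model: ModelSpec,
) -> FitResult:
    """REML on the 4800 base-cohort records via the fast reduced animal
    model (founder parents without records, complete cages)."""
    from .nucleus import fit_nucleus_reml

    sire_of = {int(a): int(pop.sire[a]) for a in cohort}
    dam_of = {int(a): int(pop.dam[a]) for a in cohort}
    return fit_nucleus_reml(
        records, model, sire_of, dam_of, init="moments",
        max_evaluations=REML_MAX_EVALUATIONS, restarts=REML_RESTARTS,
        restart_tol=REML_RESTART_TOL,
    )


def simulate_base_generation(
    params: GeneticParameters, config: SimulationConfig, seed
) -> tuple[Population, np.ndarray, pd.DataFrame, list[tuple[int, int]]]:
    """Founders, base cohort, cages and phenotypes (generation 0)."""
    pop, sires, dams = simulate_founders(params, config, [seed, 0, 0])
    matings = _founder_matings(sires, dams, config, np.random.default_rng([seed, 0, 1]))
    cohort = mate_and_drop(pop, matings, params, config, 0, [seed, 0, 2])
    groups = assign_groups(pop, cohort, config, [seed, 0, 3])
    records = generate_phenotypes(
        pop, cohort, groups, params, config, [seed, 0, 4]
    )
    return pop, cohort, records, matings


def _founder_matings(
    sires: np.ndarray, dams: np.ndarray, config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    dams = rng.permutation(dams)
    out = []
    for i, s in enumerate(sires):
        for d in dams[i * config.dams_per_sire : (i + 1) * config.dams_per_sire]:
            out.append((int(s), int(d)))
    return out


def run_scenario(
    params: GeneticParameters,
    config: SimulationConfig,
    scenario: int,
    seed: int,
    fit: FitResult | None = None,
    base: tuple | None = None,
    model: ModelSpec | None = None,
    criterion_override: str | None = None,
) -> ScenarioResult:
    """One replicate of one selection scenario.

    Variance components are estimated once on the base cohort (or taken
    from ``fit``), fixed, and used for EBV prediction in every
    generation.  ``base`` allows sharing the generated base population
    across scenarios of the same replicate (common random numbers).
    """
    if scenario not in (1, 2, 3):
        raise ValueError("scenario must be 1, 2 or 3")
    include_ige = scenario in (2, 3)
    if model is None:
        model = default_model_spec(include_ige=include_ige)
    if base is None:
        base = simulate_base_generation(params, config, seed)
    pop_template, cohort0, records0, _ = base
    # deep-copy the population so scenarios do not interfere
    pop = Population(
        sire=list(pop_template.sire),
        dam=list(pop_template.dam),
        sex_male=list(pop_template.sex_male),
        generation=list(pop_template.generation),
        bv_rows=list(pop_template.bv_rows),
    )
    J = params.n_weeks

    if fit is None:
        fit = fit_base_cohort(records0, pop, cohort0, model)
    omega = fit.estimates

    n_gen = config.n_generations
    mean_adg = np.zeros(n_gen + 1)
    weekly = np.zeros((n_gen + 1, J))
    adg0 = records0["adg"].to_numpy()
    mean_adg[0] = adg0.mean()
    weekly[0] = records0.groupby("week")["adg"].mean().to_numpy()

    all_records = records0
    cohort = cohort0
    for gen in range(1, n_gen + 1):
        eval_records = (
            all_records
            if config.evaluation_window == "cumulative"
            else all_records[all_records["animal"].isin(cohort)]
        )
        if criterion_override == "random":
            # selection decoupled from breeding values (drift baseline)
            criterion = np.random.default_rng([seed, gen, 6]).normal(
                size=len(cohort)
            )
        else:
            blup = predict_blup(eval_records, model, pop.pedigree(), omega)
            criterion = _selection_criterion(
                blup.ebv, cohort, scenario, config.group_size, J
            )
        _, _, matings = select_breeders(
            pop, cohort, criterion, config, [seed, gen, 5]
        )
        cohort = mate_and_drop(
            pop, matings, params, config, gen, [seed, gen, 2]
        )
        groups = assign_groups(pop, cohort, config, [seed, gen, 3])
        records = generate_phenotypes(
            pop, cohort, groups, params, config, [seed, gen, 4],
            group_id_offset=gen * 100000,
        )
        mean_adg[gen] = records["adg"].mean()
        weekly[gen] = records.groupby("week")["adg"].mean().to_numpy()
        all_records = pd.concat([all_records, records], ignore_index=True)

    return ScenarioResult(
        scenario=scenario,
        antagonism=params.antagonism,
        mean_adg=mean_adg,
        weekly_mean=weekly,
        fit=fit,
        converged=fit.converged,
    )


def _selection_criterion(
    ebv: pd.DataFrame, cohort: np.ndarray, scenario: int, group_size: int,
    J: int,
) -> np.ndarray:
    sub = ebv[ebv["animal"].isin(cohort)]
    piv_d = sub.pivot(index="animal", columns="week", values="dge_ebv")
    piv_d = piv_d.reindex(cohort)
    if scenario == 1:
        return piv_d.sum(axis=1).to_numpy()
    piv_i = sub.pivot(index="animal", columns="week", values="ige_ebv")
    piv_i = piv_i.reindex(cohort)
    tebv = compute_tebv(piv_d.to_numpy(), piv_i.to_numpy(), group_size)
    if scenario == 2:
        return tebv[:, 0]
    return tebv.sum(axis=1)


# ---------------------------------------------------------------------------
# parameter-recovery study (estimator bias and dispersion)


def _corr_from_cov(S: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.diag(S))
    return S / np.outer(sd, sd)


def _upper(S: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(S.shape[0], k=1)
    return S[iu]


def recovery_summary(
    estimates: list[dict[str, np.ndarray]], params: GeneticParameters
) -> pd.DataFrame:
    """Table of bias and dispersion of variance-component estimates.

    For variances: mean relative bias (E(est)-true)/true x 100 and the
    coefficient of variation sd(est)/E(est) x 100, averaged over the
    5 weeks (with the range).  For correlations: mean bias E(est)-true
    and the SD of the estimates, averaged over the 10 within-effect (or
    25 cross) week pairs.
    """
    J = params.n_weeks
    truth_ge = params.sigma_ge
    Rt = _corr_from_cov(truth_ge)
    rows = []

    def collect(name, true_vals, est_vals, relative):
        est = np.asarray(est_vals)           # (reps, k)
        true = np.asarray(true_vals)         # (k,)
        mean = est.mean(axis=0)
        sd = est.std(axis=0, ddof=1) if est.shape[0] > 1 else np.zeros_like(mean)
        if relative:
            bias = (mean - true) / true * 100.0
            disp = np.where(mean != 0, sd / np.abs(mean) * 100.0, 0.0)
            bias_lab, disp_lab = "relative_bias_pct", "cv_pct"
        else:
            bias = mean - true
            disp = sd
            bias_lab, disp_lab = "bias", "sd"
        rows.append(
            {
                "component": name,
                "criterion": bias_lab,
                "average": bias.mean(),
                "min": bias.min(),
                "max": bias.max(),
            }
        )
        rows.append(
            {
                "component": name,
                "criterion": disp_lab,
                "average": disp.mean(),
                "min": disp.min(),
                "max": disp.max(),
            }
        )

    ge = np.stack([e["genetic"] for e in estimates])
    grp = np.stack([e["group"] for e in estimates])
    dvar = ge[:, np.arange(J), np.arange(J)]
    ivar = ge[:, J + np.arange(J), J + np.arange(J)]
    collect("direct_genetic_variance", np.diag(truth_ge)[:J], dvar, True)
    corr = np.stack([_corr_from_cov(S) for S in ge])
    collect(
        "direct_genetic_correlation",
        _upper(Rt[:J, :J]),
        np.stack([_upper(R[:J, :J]) for R in corr]),
        False,
    )
    collect("indirect_genetic_variance", np.diag(truth_ge)[J:], ivar, True)
    collect(
        "indirect_genetic_correlation",
        _upper(Rt[J:, J:]),
        np.stack([_upper(R[J:, J:]) for R in corr]),
        False,
    )
    collect(
        "direct_indirect_correlation",
        Rt[:J, J:].ravel(),
        np.stack([R[:J, J:].ravel() for R in corr]),
        False,
    )
    collect(
        "group_variance",
        np.diag(params.sigma_group),
        grp[:, np.arange(J), np.arange(J)],
        True,
    )
    Rg = _corr_from_cov(params.sigma_group)
    collect(
        "group_correlation",
        _upper(Rg),
        np.stack([_upper(_corr_from_cov(S)) for S in grp]),
        False,
    )
    return pd.DataFrame(rows)


def recovery_study(
    params: GeneticParameters,
    config: SimulationConfig,
    replicates: int,
    seed: int,
    fitter=None,
    model: ModelSpec | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Repeatedly simulate the base cohort and re-estimate components.

    ``fitter(records, ped, model)`` may be supplied for testing (e.g. an
    oracle returning the truth); the default runs REML.  Non-converged
    replicates are excluded and their fraction reported.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    if model is None:
        model = default_model_spec(include_ige=True)
    estimates = []
    n_converged = 0
    fits = []
    for rep in range(replicates):
        rep_seed = seed + rep
        pop, cohort, records, _ = simulate_base_generation(
            params, config, rep_seed
        )
        if fitter is not None:
            covs, converged = fitter(records, pop.pedigree(), model)
        else:
            fit = fit_base_cohort(records, pop, cohort, model)
            covs = fit.covariance_matrices()
            converged = fit.converged and not fit.at_boundary
            fits.append(fit)
        if converged:
            estimates.append(covs)
            n_converged += 1
    if n_converged < 2:
        raise RuntimeError("fewer than 2 converged replicates")
    table = recovery_summary(estimates, params)
    meta = {
        "replicates": replicates,
        "converged": n_converged,
        "pct_used": 100.0 * n_converged / replicates,
        "fits": fits,
    }
    return table, meta
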
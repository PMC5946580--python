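"""Synthetic rabbit-like longitudinal growth datasets.

Generates data with the statistical structure the analysis model
assumes: a two-generation pedigree of unrelated parents and full-sib
litters, weaned kits housed in cages of eight (four litters x two kits
by default), five weekly ADG records per animal, and random effects
drawn from their model distributions — genetic (direct + indirect,
``A x Sigma_GE`` via pedigree-recursive sampling), litter, group and
pseudo-permanent (which doubles as the residual).  Attrition removes
whole cages from a week onward, mirroring the practice of discarding
groups hit by disease or death; per-animal dropout is available behind
a flag.

The returned truth record carries every simulated effect so that
parameter-recovery and prediction-accuracy checks can compare against
the generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import params as default_params
from .pedigree import Pedigree, mendelian_variance_scalars

__all__ = ["DatasetSpec", "generate_dataset", "pedigree_aware_mvn_sample"]


def _mvn(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    """MVN(0, cov) draws via the eigendecomposition (PSD-safe)."""
    w, V = np.linalg.eigh((cov + cov.T) / 2.0)
    root = V * np.sqrt(np.maximum(w, 0.0))
    return rng.standard_normal((size, cov.shape[0])) @ root.T


@dataclass
class DatasetSpec:
    """Design and parameter bundle for one synthetic dataset.

    Defaults emulate the published experiment's shape: 387 cages of 8
    (≈3,100 phenotyped kits), five weekly records, cage-level attrition
    calibrated to the observed decline of weekly record counts
    (~2,700 week-1 records falling to ~1,700 by week 5).
    """

    n_cages: int = 387
    cage_size: int = 8
    litters_per_cage: int = 4
    n_weeks: int = 5
    sigma_ge: np.ndarray = field(
        default_factory=default_params.default_genetic_covariance
    )
    sigma_litter: np.ndarray = field(
        default_factory=default_params.default_litter_covariance
    )
    sigma_group: np.ndarray = field(
        default_factory=default_params.default_group_covariance
    )
    sigma_perm: np.ndarray = field(
        default_factory=default_params.default_permanent_covariance
    )
    week_means: np.ndarray = field(
        default_factory=lambda: default_params.WEEK_MEANS.copy()
    )
    #: probability that a cage is lost from week j onward (first entry:
    #: lost before any record); calibrated to the published record counts
    attrition: tuple[float, ...] = (0.132, 0.023, 0.111, 0.108, 0.072)
    per_animal_attrition: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cage_size % self.litters_per_cage:
            raise ValueError("cage_size must be divisible by litters_per_cage")
        for name in ("sigma_ge", "sigma_litter", "sigma_group", "sigma_perm"):
            M = np.asarray(getattr(self, name), dtype=float)
            if np.linalg.eigvalsh((M + M.T) / 2)[0] < -1e-8 * max(
                np.trace(M), 1.0
            ):
                raise ValueError(f"{name} is not positive semi-definite")
        if len(self.attrition) != self.n_weeks:
            raise ValueError("need one attrition probability per week")

    @property
    def kits_per_litter(self) -> int:
        return self.cage_size // self.litters_per_cage

    @property
    def n_animals(self) -> int:
        return self.n_cages * self.cage_size


def pedigree_aware_mvn_sample(
    ped: Pedigree, sigma: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Sample effect trajectories with covariance ``A x sigma``.

    Uses the pedigree recursion (parent average plus a Mendelian
    deviation scaled by the Meuwissen-Luo variance scalar), so the cost
    is linear in the number of animals rather than cubic in ``A``.
    """
    rng = np.random.default_rng(seed)
    k = sigma.shape[0]
    w, V = np.linalg.eigh((sigma + sigma.T) / 2.0)
    root = V @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    d = mendelian_variance_scalars(ped)
    noise = rng.standard_normal((ped.n, k)) @ root.T
    out = np.zeros((ped.n, k))
    for i in range(ped.n):
        val = np.sqrt(d[i]) * noise[i]
        if ped.sire[i] >= 0:
            val = val + 0.5 * out[ped.sire[i]]
        if ped.dam[i] >= 0:
            val = val + 0.5 * out[ped.dam[i]]
        out[i] = val
    return out


def _build_pedigree(spec: DatasetSpec) -> tuple[Pedigree, np.ndarray, np.ndarray]:
    """Two-generation pedigree: unrelated parents, full-sib litters.

    Each litter has its own dam; sires serve four litters (half-sib
    structure across litters, as in a standard insemination batch).
    Returns the pedigree plus per-kit litter index and kit rows.
    """
    litters_total = spec.n_cages * spec.litters_per_cage
    n_sires = -(-litters_total // 4)
    n_dams = litters_total
    ids: list = []
    sire_idx = []
    dam_idx = []
    for s in range(n_sires):
        ids.append(f"S{s}")
        sire_idx.append(-1)
        dam_idx.append(-1)
    for d_ in range(n_dams):
        ids.append(f"D{d_}")
        sire_idx.append(-1)
        dam_idx.append(-1)
    kit_rows = []
    kit_litter = []
    row = n_sires + n_dams
    for lit in range(litters_total):
        s_row = lit // 4
        d_row = n_sires + lit
        for k in range(spec.kits_per_litter):
            ids.append(f"K{lit}_{k}")
            sire_idx.append(s_row)
            dam_idx.append(d_row)
            kit_rows.append(row)
            kit_litter.append(lit)
            row += 1
    ped = Pedigree(
        tuple(ids),
        np.asarray(sire_idx, dtype=np.int64),
        np.asarray(dam_idx, dtype=np.int64),
    )
    return ped, np.asarray(kit_litter), np.asarray(kit_rows)


def generate_dataset(
    spec: DatasetSpec,
) -> tuple[Pedigree, pd.DataFrame, dict]:
    """Generate (pedigree, phenotype table, truth record).

    The phenotype table has columns (animal, litter, group, week, adg);
    the truth record carries the simulated per-animal genetic
    trajectories and all other effect draws, plus the attrition map.
    """
    rng = np.random.default_rng(spec.seed)
    J = spec.n_weeks
    ped, kit_litter, kit_rows = _build_pedigree(spec)
    n_kits = len(kit_rows)

    bv = pedigree_aware_mvn_sample(ped, spec.sigma_ge, rng)
    litters_total = spec.n_cages * spec.litters_per_cage
    lit_eff = _mvn(rng, spec.sigma_litter, litters_total)
    grp_eff = _mvn(rng, spec.sigma_group, spec.n_cages)
    perm_eff = _mvn(rng, spec.sigma_perm, n_kits)

    # cage assignment: a random chunk of `litters_per_cage` litters
    # fills one cage, each litter contributing its kits_per_litter kits
    cage_of = np.full(n_kits, -1, dtype=np.int64)
    order = rng.permutation(litters_total)
    for cage in range(spec.n_cages):
        chunk = order[
            cage * spec.litters_per_cage : (cage + 1) * spec.litters_per_cage
        ]
        for lit in chunk:
            cage_of[np.flatnonzero(kit_litter == lit)] = cage

    # weekly phenotypes
    dge = bv[kit_rows, :J]
    ige = bv[kit_rows, J:]
    ige_sum = np.zeros_like(ige)
    for c in range(spec.n_cages):
        members = np.flatnonzero(cage_of == c)
        tot = ige[members].sum(axis=0)
        ige_sum[members] = tot - ige[members]
    y = (
        np.asarray(spec.week_means)[None, :]
        + dge
        + ige_sum
        + grp_eff[cage_of]
        + lit_eff[kit_litter]
        + perm_eff
    )

    # attrition: whole cages leave from a week onward (monotone dropout)
    last_week = np.full(spec.n_cages, J, dtype=np.int64)
    for c in range(spec.n_cages):
        for j in range(J):
            if rng.random() < spec.attrition[j]:
                last_week[c] = j
                break
    observed = np.ones((n_kits, J), dtype=bool)
    for c in range(spec.n_cages):
        members = np.flatnonzero(cage_of == c)
        observed[members, last_week[c]:] = False
    if spec.per_animal_attrition:
        # optional additional independent per-animal dropout
        drop = rng.random((n_kits, J)) < np.asarray(spec.attrition)[None, :]
        observed &= ~np.cumsum(drop, axis=1).astype(bool)

    rows = []
    animal_ids = [ped.ids[r] for r in kit_rows]
    for i in range(n_kits):
        for j in range(J):
            if observed[i, j]:
                rows.append(
                    (
                        animal_ids[i],
                        f"L{kit_litter[i]}",
                        f"C{cage_of[i]}",
                        j + 1,
                        y[i, j],
                    )
                )
    table = pd.DataFrame(
        rows, columns=["animal", "litter", "group", "week", "adg"]
    )
    truth = {
        "bv": bv,
        "kit_rows": kit_rows,
        "dge": dge,
        "ige": ige,
        "litter_effects": lit_eff,
        "group_effects": grp_eff,
        "permanent_effects": perm_eff,
        "cage_of": cage_of,
        "kit_litter": kit_litter,
        "observed": observed,
        "cage_last_week": last_week,
    }
    return ped, table, truth
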
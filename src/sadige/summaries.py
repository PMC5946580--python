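"""Variance partition, heritabilities and sampling-based standard errors.

For a group of ``n`` animals the phenotypic variance at week ``j``
partitions as::

    sigma2_T = sigma2_DGE + (n-1) sigma2_IGE
               + (n-1) r [2 sigma_DGE,IGE + (n-2) sigma2_IGE]
               + sigma2_litter + sigma2_group + sigma2_perm

where ``r`` is the average additive relatedness among cage mates (the
relatedness terms arise because related cage mates correlate the focal
direct effect with received indirect effects).  The total breeding
value of an animal is its direct effect plus ``(n-1)`` times its
indirect effect, so the total heritable variance is::

    sigma2_TBV = sigma2_DGE + 2(n-1) sigma_DGE,IGE + (n-1)^2 sigma2_IGE

(14 and 49 for the default group size of 8).  Heritabilities are
ratios to sigma2_T: direct ``sigma2_DGE / sigma2_T``, indirect
``(n-1)^2 sigma2_IGE / sigma2_T`` and total ``sigma2_TBV / sigma2_T``.
Indirect and total heritabilities are variance ratios of *derived*
quantities and may legitimately exceed 1.

Standard errors come from multivariate-normal sampling of the REML
estimates: omega ~ N(omega_hat, H(omega_hat)) with H the inverse
information matrix, rebuilding every covariance matrix per draw and
discarding draws yielding non-positive-semi-definite matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed_model import FitResult

__all__ = [
    "VariancePartition",
    "total_phenotypic_variance",
    "total_heritable_variance",
    "heritabilities",
    "partition_from_fit",
    "mvn_sampling_se",
    "estimate_correlations",
]

#: PSD tolerance for rejecting sampled covariance matrices
PSD_TOL = 1e-8


@dataclass
class VariancePartition:
    """Per-week variance components, (g/d)^2."""

    dge: np.ndarray
    ige: np.ndarray
    dge_ige: np.ndarray
    litter: np.ndarray
    group: np.ndarray
    permanent: np.ndarray
    n_group: int = 8
    relatedness: float = 0.16

    def __post_init__(self) -> None:
        J = len(self.dge)
        for name in ("ige", "dge_ige", "litter", "group", "permanent"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (J,):
                raise ValueError(f"component {name} has wrong length")
            setattr(self, name, arr)
        self.dge = np.asarray(self.dge, dtype=float)

    @property
    def n_weeks(self) -> int:
        return len(self.dge)


def total_phenotypic_variance(part: VariancePartition) -> np.ndarray:
    """Phenotypic variance per week for the given group size and
    cage-mate relatedness."""
    n, r = part.n_group, part.relatedness
    return (
        part.dge
        + (n - 1) * part.ige
        + (n - 1) * r * (2.0 * part.dge_ige + (n - 2) * part.ige)
        + part.litter
        + part.group
        + part.permanent
    )


def total_heritable_variance(part: VariancePartition) -> np.ndarray:
    """Variance of total breeding values per week."""
    n = part.n_group
    return part.dge + 2 * (n - 1) * part.dge_ige + (n - 1) ** 2 * part.ige


def heritabilities(part: VariancePartition) -> pd.DataFrame:
    """Direct, indirect and total heritability per week.

    Values are reported as computed — negative or >1 ratios flag
    pathological component combinations rather than being clamped.
    """
    tot = total_phenotypic_variance(part)
    if np.any(tot <= 0):
        raise ValueError("total phenotypic variance must be positive")
    n = part.n_group
    return pd.DataFrame(
        {
            "week": np.arange(1, part.n_weeks + 1),
            "direct_h2": part.dge / tot,
            "indirect_h2": (n - 1) ** 2 * part.ige / tot,
            "total_h2": total_heritable_variance(part) / tot,
            "total_variance": tot,
        }
    )


def partition_from_matrices(
    covs: dict[str, np.ndarray],
    n_group: int = 8,
    relatedness: float = 0.16,
) -> VariancePartition:
    """Extract per-week components from effect covariance matrices.

    ``covs["genetic"]`` is JxJ (direct only) or 2Jx2J ([DGE, IGE]
    blocks); missing litter/group matrices contribute zeros.
    """
    G = covs["genetic"]
    if G.shape[0] % 2 == 0 and G.shape[0] > 5:
        J = G.shape[0] // 2
        dge = np.diag(G)[:J]
        ige = np.diag(G)[J:]
        dge_ige = np.diag(G[:J, J:])
    else:
        J = G.shape[0]
        dge = np.diag(G)
        ige = np.zeros(J)
        dge_ige = np.zeros(J)
    zero = np.zeros(J)
    return VariancePartition(
        dge=dge,
        ige=ige,
        dge_ige=dge_ige,
        litter=np.diag(covs["litter"]) if "litter" in covs else zero,
        group=np.diag(covs["group"]) if "group" in covs else zero,
        permanent=np.diag(covs["permanent"]),
        n_group=n_group,
        relatedness=relatedness,
    )


def partition_from_fit(
    fit: FitResult, n_group: int = 8, relatedness: float = 0.16
) -> VariancePartition:
    return partition_from_matrices(
        fit.covariance_matrices(), n_group, relatedness
    )


def _is_psd(M: np.ndarray) -> bool:
    ev = np.linalg.eigvalsh((M + M.T) / 2.0)
    return bool(ev[0] >= -PSD_TOL * max(np.trace(M), 1.0))


@dataclass
class SamplingSummary:
    """Output of the MVN sampling pass over the parameter estimates."""

    heritability: pd.DataFrame          # means with _se columns
    component_means: dict[str, np.ndarray]
    component_ses: dict[str, np.ndarray]
    n_retained: int
    n_rejected: int
    draws_components: dict[str, np.ndarray]   # retained raw draws
    draws_omega: np.ndarray


def mvn_sampling_se(
    fit: FitResult,
    n_samples: int = 10_000,
    seed: int | np.random.Generator = 0,
    n_group: int = 8,
    relatedness: float = 0.16,
) -> SamplingSummary:
    """Sampling distribution of covariance and heritability estimates.

    Draws ``omega ~ N(omega_hat, H)`` with ``H`` the inverse observed
    information, rebuilds every effect covariance and the heritability
    table per draw, and drops draws with any non-PSD covariance.  Point
    estimates are the means over retained draws; standard errors their
    standard deviations.  Rejection is a pure filter — retained draws
    are never altered.
    """
    rng = np.random.default_rng(seed)
    H = fit.param_covariance
    H = (H + H.T) / 2.0
    # allow H == 0 (degenerate, all draws at omega_hat)
    ev = np.linalg.eigvalsh(H)
    if ev[0] < -1e-8 * max(np.trace(H), 1e-300):
        raise ValueError("parameter covariance is not PSD")
    w, V = np.linalg.eigh(H)
    root = V @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    draws = fit.estimates[None, :] + rng.standard_normal(
        (n_samples, fit.n_params)
    ) @ root.T

    kept_components: dict[str, list[np.ndarray]] = {}
    kept_herit: list[np.ndarray] = []
    kept_omega: list[np.ndarray] = []
    n_rej = 0
    n = n_group
    for om in draws:
        try:
            covs = fit.model.unpack(om).covariance_matrices()
        except (OverflowError, np.linalg.LinAlgError):
            n_rej += 1
            continue
        if not all(_is_psd(M) for M in covs.values()):
            n_rej += 1
            continue
        part = partition_from_matrices(covs, n_group, relatedness)
        tot = total_phenotypic_variance(part)
        if np.any(tot <= 0):
            n_rej += 1
            continue
        # heritability ratios computed inline (the DataFrame wrapper is
        # far too slow inside a 10^4-draw loop)
        tbv = part.dge + 2 * (n - 1) * part.dge_ige + (n - 1) ** 2 * part.ige
        kept_herit.append(
            np.column_stack(
                [part.dge / tot, (n - 1) ** 2 * part.ige / tot, tbv / tot]
            )
        )
        kept_omega.append(om)
        for name, M in covs.items():
            kept_components.setdefault(name, []).append(M)
    if not kept_herit:
        raise RuntimeError(
            "all MVN samples rejected: estimates sit on the PSD boundary "
            f"({n_samples} draws, information condition "
            "suggests weak identifiability)"
        )
    herit = np.stack(kept_herit)              # (kept, J, 3)
    J = herit.shape[1]
    out = pd.DataFrame({"week": np.arange(1, J + 1)})
    for i, col in enumerate(("direct_h2", "indirect_h2", "total_h2")):
        out[col] = herit[:, :, i].mean(axis=0)
        out[col + "_se"] = herit[:, :, i].std(axis=0, ddof=1) if len(
            kept_herit
        ) > 1 else 0.0
    comp_draws = {k: np.stack(v) for k, v in kept_components.items()}
    return SamplingSummary(
        heritability=out,
        component_means={k: v.mean(axis=0) for k, v in comp_draws.items()},
        component_ses={
            k: (v.std(axis=0, ddof=1) if v.shape[0] > 1 else np.zeros_like(v[0]))
            for k, v in comp_draws.items()
        },
        n_retained=len(kept_herit),
        n_rejected=n_rej,
        draws_components=comp_draws,
        draws_omega=np.stack(kept_omega),
    )


def estimate_correlations(
    fit: FitResult,
    n_samples: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> dict[str, pd.DataFrame]:
    """Correlations among (co)variance-component estimates and among the
    raw parameter estimates.

    High absolute correlations (> 0.6 is the conventional flag) mark
    parameter pairs the data cannot separate.  Warns (via the returned
    metadata) when fewer than 100 draws survive the PSD filter.
    """
    summary = mvn_sampling_se(fit, n_samples=n_samples, seed=seed)
    labels: list[str] = []
    cols: list[np.ndarray] = []
    for name, draws in sorted(summary.draws_components.items()):
        k = draws.shape[1]
        iu = np.triu_indices(k)
        for i, j in zip(*iu):
            labels.append(f"{name}[{i + 1},{j + 1}]")
        cols.append(draws[:, iu[0], iu[1]])
    mat = np.hstack(cols)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    np.fill_diagonal(corr, 1.0)
    comp = pd.DataFrame(corr, index=labels, columns=labels)
    with np.errstate(invalid="ignore"):
        oc = np.corrcoef(summary.draws_omega, rowvar=False)
    oc = np.where(np.isfinite(oc), oc, 0.0)
    np.fill_diagonal(oc, 1.0)
    om_lab = [f"omega_{i}" for i in range(fit.n_params)]
    return {
        "components": comp,
        "omega": pd.DataFrame(oc, index=om_lab, columns=om_lab),
        "n_retained": summary.n_retained,
        "low_sample_warning": summary.n_retained < 100,
    }
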
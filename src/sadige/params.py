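"""Default variance-component values for simulation and synthetic data.

The bundled matrices describe a rabbit fattening design: five weekly
ADG records (g/d) per animal, cages of eight, direct and indirect
genetic effects antagonistically correlated.  Each matrix is the
covariance implied by a SAD1-11 covariance function (order-1
antedependence, degree-1 coefficient and log-innovation-variance
polynomials; the genetic pair adds a degree-1 cross-antedependence
term) whose coefficients were calibrated once, by weighted least
squares, to the published weekly variance levels and correlation
patterns for this design:

* direct genetic variance rising from ~8 to ~13 (g/d)^2 by week 3 and
  falling to ~6 by week 5; between-week correlations 0.5-0.9 decaying
  with the time interval;
* indirect genetic variance ~0.44 falling to ~0.25 with a week-5
  uptick; week-1 IGE only weakly correlated with later weeks
  (hierarchy establishment), weeks 2-5 strongly correlated;
* direct-indirect correlations negative everywhere (-0.35 to -0.8);
* group variance rising ~5.7 to ~16.4 with weakly negative
  consecutive-week correlations;
* pseudo-permanent variance rising ~23 to ~53, near-zero between-week
  correlations;
* litter variance falling ~8.7 to ~4.2 with positive correlations.

Because the generating covariances sit on the SAD manifold (as they do
when a simulation is parameterized from a fitted SAD model), the
estimation model used downstream is only mildly misspecified — the
cross-block rescaling used for the antagonism levels moves the truth
slightly off the manifold.
"""

from __future__ import annotations

import numpy as np

from .sad import (
    CrossSADSpec,
    PolyFn,
    SADSpec,
    TimeGrid,
    build_cross_sigma,
    sigma_from_spec,
)

__all__ = [
    "WEEK_MEANS",
    "PARAM_GRID",
    "default_genetic_covariance",
    "default_group_covariance",
    "default_permanent_covariance",
    "default_litter_covariance",
    "nearest_psd",
    "scale_cross_block",
]

#: weekly mean ADG (g/d) under restricted feeding
WEEK_MEANS = np.array([26.5, 37.5, 42.0, 40.1, 41.2])

#: centred time coding used by the calibrated covariance functions
PARAM_GRID = TimeGrid((1, 2, 3, 4, 5), shift=3.0)

# calibrated SAD1-11 coefficients (constant, slope) on the centred grid
_GENETIC_SPEC = CrossSADSpec(
    primary_spec=SADSpec(
        (PolyFn((0.758226, -0.043223)),), PolyFn((0.900212, -0.097192))
    ),
    secondary_spec=SADSpec(
        (PolyFn((0.715161, 0.169900)),), PolyFn((-2.396656, -0.791693))
    ),
    cross_fn=PolyFn((-1.568011, 0.841727)),
)
_GROUP_SPEC = SADSpec(
    (PolyFn((-0.338947, 0.065350)),), PolyFn((2.273958, 0.259199))
)
_PERMANENT_SPEC = SADSpec(
    (PolyFn((-0.168465, 0.018369)),), PolyFn((3.577179, 0.203059))
)
_LITTER_SPEC = SADSpec(
    (PolyFn((0.592365, 0.071905)),), PolyFn((1.279888, -0.434067))
)


def default_genetic_covariance() -> np.ndarray:
    """10x10 genetic covariance [DGE w1-5, IGE w1-5], strong antagonism."""
    return build_cross_sigma(_GENETIC_SPEC, PARAM_GRID)


def default_group_covariance() -> np.ndarray:
    return sigma_from_spec(_GROUP_SPEC, PARAM_GRID)


def default_permanent_covariance() -> np.ndarray:
    return sigma_from_spec(_PERMANENT_SPEC, PARAM_GRID)


def default_litter_covariance() -> np.ndarray:
    return sigma_from_spec(_LITTER_SPEC, PARAM_GRID)


def nearest_psd(M: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped positive semi-definite approximation.

    For correlation matrices the unit diagonal is restored after
    clipping (one-step Higham-style repair).
    """
    M = (M + M.T) / 2.0
    w, V = np.linalg.eigh(M)
    w = np.maximum(w, eps)
    R = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    return (R + R.T) / 2.0


def scale_cross_block(sigma_ge: np.ndarray, divisor: float) -> np.ndarray:
    """Rescale the DGE-IGE cross block (antagonism strength).

    Dividing the cross block by ``k >= 1`` is a convex combination of
    the original matrix and its block-diagonal part, hence preserves
    positive semi-definiteness.
    """
    if divisor < 1.0:
        raise ValueError("divisor must be >= 1 to preserve PSD")
    J = sigma_ge.shape[0] // 2
    out = sigma_ge.copy()
    out[:J, J:] /= divisor
    out[J:, :J] /= divisor
    ev = np.linalg.eigvalsh(out)
    if ev[0] < -1e-8 * np.trace(out):
        raise ValueError("antagonism scaling produced a non-PSD matrix")
    return out
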
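"""Step-length prediction from cadence, height and DMD status.

The model is a linear regression on transformed covariates: square-root
cadence u = sqrt(sf) and inverse-square-root height v = 1/sqrt(h), with a
full set of DMD-interaction terms:

    SL = b_sf*u + b_h*v + b_sf_h*u*v + b_0
         + dmd * (d_0 + d_sf*u + d_h*v + d_sf_h*u*v)

where sf is step frequency in steps/s, h standing height in meters and dmd
an indicator (1 = Duchenne muscular dystrophy, 0 = typically developing).
The published coefficients (``EQ1_COEFFICIENTS``) were calibrated on
multi-speed overground walking trials in children aged 3-16; at matched
cadence and height the DMD terms lower the predicted step length.

:func:`fit_step_length_model` refits the same eight-term design by ordinary
least squares, for recovery experiments and recalibration on new cohorts.
The original calibration used mixed-effects regression with within-subject
random effects; the fixed-effects fit here does not reproduce that structure
and the fit report says so.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger(__name__)

_TERM_NAMES = ["b_sf", "b_h", "b_sf_h", "b_0", "d_0", "d_sf", "d_h", "d_sf_h"]


@dataclass(frozen=True)
class StepLengthCoefficients:
    """The eight coefficients of the step-length regression (meters scale).

    ``b_*`` apply to everyone; ``d_*`` are added for DMD participants.
    """

    b_sf: float
    b_h: float
    b_sf_h: float
    b_0: float
    d_0: float
    d_sf: float
    d_h: float
    d_sf_h: float

    def __post_init__(self) -> None:
        for name in _TERM_NAMES:
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"coefficient {name} is not finite")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _TERM_NAMES], dtype=float)


#: Published coefficients of the step-length equation.
EQ1_COEFFICIENTS = StepLengthCoefficients(
    b_sf=3.33758,
    b_h=2.442582,
    b_sf_h=-3.072612,
    b_0=-2.505019,
    d_0=1.87948,
    d_sf=-1.689478,
    d_h=-1.865428,
    d_sf_h=1.664073,
)


@dataclass(frozen=True)
class StepObservation:
    """One trial-level observation for model fitting."""

    step_frequency: float
    height: float
    dmd: int
    step_length: float


def predict_step_length(
    sf, h, dmd, coefficients: StepLengthCoefficients = EQ1_COEFFICIENTS
):
    """Predicted step length in meters.

    Vectorized over ``sf``.  ``sf == 0`` (an inactive window) predicts 0 m;
    negative predictions (possible at very low cadence for DMD subjects) are
    clamped to 0 with a logged warning.
    """
    sf = np.asarray(sf, dtype=float)
    if np.any(sf < 0):
        raise ValueError("step frequency must be nonnegative")
    h = float(h)
    if h <= 0:
        raise ValueError(f"height must be positive, got {h}")
    if dmd not in (0, 1):
        raise ValueError(f"dmd must be 0 or 1, got {dmd!r}")
    c = coefficients
    u = np.sqrt(sf)
    v = 1.0 / np.sqrt(h)
    sl = c.b_sf * u + c.b_h * v + c.b_sf_h * u * v + c.b_0
    if dmd:
        sl = sl + c.d_0 + c.d_sf * u + c.d_h * v + c.d_sf_h * u * v
    sl = np.where(sf == 0.0, 0.0, sl)
    if np.any(sl < 0):
        logger.warning("clamping %d negative step-length predictions to 0", int(np.sum(sl < 0)))
        sl = np.clip(sl, 0.0, None)
    return float(sl) if sl.ndim == 0 else sl


def design_matrix(sf: np.ndarray, h: np.ndarray, dmd: np.ndarray) -> np.ndarray:
    """Eight-column design {u, v, u*v, 1, dmd, dmd*u, dmd*v, dmd*u*v}."""
    u = np.sqrt(np.asarray(sf, dtype=float))
    v = 1.0 / np.sqrt(np.asarray(h, dtype=float))
    dmd = np.asarray(dmd, dtype=float)
    one = np.ones_like(u)
    return np.column_stack([u, v, u * v, one, dmd, dmd * u, dmd * v, dmd * u * v])


@dataclass(frozen=True)
class StepLengthFit:
    """Least-squares refit of the eight-term step-length model.

    ``rmse`` is the residual root-mean-square error with degrees-of-freedom
    correction (sqrt(SSR / (n - 8))); ``r2_adj`` the adjusted R^2.  This is a
    pooled fixed-effects fit: within-subject random effects of the original
    calibration are not modeled.
    """

    coefficients: StepLengthCoefficients
    rmse: float
    r2_adj: float
    n_obs: int
    note: str = "pooled fixed-effects OLS; within-subject random effects not modeled"


def fit_step_length_model(observations) -> StepLengthFit:
    """Fit the eight-term transformed regression by ordinary least squares.

    Requires >= 20 observations and both DMD groups present (the interaction
    terms are otherwise unidentifiable).
    """
    obs = list(observations)
    if len(obs) < 20:
        raise ValueError(f"need at least 20 observations, got {len(obs)}")
    sf = np.array([o.step_frequency for o in obs])
    h = np.array([o.height for o in obs])
    dmd = np.array([o.dmd for o in obs])
    y = np.array([o.step_length for o in obs])
    if np.any(sf <= 0) or np.any(y <= 0):
        raise ValueError("fitting rows require positive step frequency and step length")
    groups = set(int(d) for d in dmd)
    if groups != {0, 1}:
        raise ValueError(
            "both DMD groups must be present to estimate the DMD-interaction terms "
            f"(got only dmd={sorted(groups)})"
        )
    X = design_matrix(sf, h, dmd)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design (rank {rank} < 8); collinear transformed terms")
    res = sm.OLS(y, X).fit()
    coeffs = StepLengthCoefficients(*res.params)
    rmse = float(np.sqrt(res.ssr / res.df_resid))
    return StepLengthFit(coefficients=coeffs, rmse=rmse, r2_adj=float(res.rsquared_adj), n_obs=len(obs))
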
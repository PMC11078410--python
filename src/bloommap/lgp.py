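"""Spatiotemporal log-Gaussian-process model of chlorophyll fluorescence.

Fluorescence in bloom conditions is approximately log-normal ("hot-spot"
patchiness), so the field is modelled as a Gaussian process on the centred
log measurements

    z_S = ln y_S - m_GP,      m_GP = mean(ln y_S),

with an anisotropic squared-exponential kernel over (x, y, z, tau):

    k(s, s') = sigma_c^2 exp(-1/2 * sum_d ((s_d - s'_d) / M_d)^2),

where M = (M_x, M_y, M_z, M_tau) are per-axis de-correlation lengths (the
time axis gives measurements a decaying influence as they age) and sigma_c,
sigma_n are the process and nugget standard deviations of z. Predictions at
locations S_* evaluated at the current time tau_now follow the standard GP
posterior

    f_*bar  = K_{*,S} [K_{S,S} + sigma_n^2 I]^{-1} z_S + m_GP
    cov f_* = K_{*,*} - K_{*,S} [K_{S,S} + sigma_n^2 I]^{-1} K_{S,*}

and are mapped back to the fluorescence scale with the log-normal moment
transform

    y_hat     = exp(f_*bar + var/2)
    Sigma_y^2 = y_hat^2 (exp(var) - 1),

so the predictive variance on the measurement scale grows with the predicted
mean — high-concentration regions are intrinsically more uncertain, which the
waypoint utility exploits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial.distance import cdist

from .geometry import GridState, VolumeConfig

#: Default floor (ug/L) applied to non-positive readings before the log.
DEFAULT_VALUE_FLOOR = 0.01


@dataclass(frozen=True)
class LGPHyperparams:
    """Kernel and noise hyperparameters of the log-GP.

    ``M`` holds the de-correlation lengths (M_x, M_y, M_z metres, M_tau
    seconds); ``sigma_c`` and ``sigma_n`` are the process and nugget
    *standard deviations* of the centred log field (unitless).
    """

    M: tuple[float, float, float, float] = (600.0, 600.0, 3.0, 10_000.0)
    sigma_c: float = 1.6
    sigma_n: float = 0.7

    def __post_init__(self) -> None:
        if len(self.M) != 4 or any(m <= 0 for m in self.M):
            raise ValueError(f"de-correlation lengths must be positive, got {self.M}")
        if self.sigma_c <= 0 or self.sigma_n <= 0:
            raise ValueError("sigma_c and sigma_n must be positive")
        object.__setattr__(self, "M", tuple(float(m) for m in self.M))


def log_transform(
    y: np.ndarray, floor: float | None = DEFAULT_VALUE_FLOOR
) -> tuple[np.ndarray, float]:
    """Centre log-values: returns ``(z, m_GP)`` with ``z = ln y - mean(ln y)``.

    Values at or below zero are clipped to ``floor`` first (real fluorometers
    emit zeros); pass ``floor=None`` to disable clipping, in which case
    non-positive values raise.
    """
    y = np.asarray(y, dtype=float)
    if floor is not None:
        y = np.maximum(y, floor)
    if np.any(y <= 0):
        raise ValueError("non-positive values cannot be log-transformed")
    ln = np.log(y)
    m_gp = float(ln.mean())
    return ln - m_gp, m_gp


def kernel(
    s: np.ndarray, s_prime: np.ndarray, hp: LGPHyperparams
) -> float | np.ndarray:
    """Anisotropic squared-exponential covariance between 4-vectors (x,y,z,tau)."""
    s = np.asarray(s, dtype=float)
    s_prime = np.asarray(s_prime, dtype=float)
    d2 = np.sum(((s - s_prime) / np.asarray(hp.M)) ** 2, axis=-1)
    out = hp.sigma_c**2 * np.exp(-0.5 * d2)
    return float(out) if np.ndim(out) == 0 else out


def kernel_matrix(A: np.ndarray, B: np.ndarray, hp: LGPHyperparams) -> np.ndarray:
    """Covariance matrix between two sets of (n, 4) space-time points."""
    M = np.asarray(hp.M)
    d2 = cdist(np.asarray(A, float) / M, np.asarray(B, float) / M, "sqeuclidean")
    return hp.sigma_c**2 * np.exp(-0.5 * d2)


def lognormal_moments(
    f_star_mean: np.ndarray, f_star_var: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of exp(N(f_star_mean, f_star_var)).

    Maps log-space GP predictions back to the fluorescence scale.
    """
    f_star_mean = np.asarray(f_star_mean, dtype=float)
    f_star_var = np.asarray(f_star_var, dtype=float)
    if np.any(f_star_var < 0):
        raise ValueError("variance must be non-negative")
    y_hat = np.exp(f_star_mean + f_star_var / 2.0)
    sigma_y2 = y_hat**2 * (np.exp(f_star_var) - 1.0)
    return y_hat, sigma_y2


@dataclass(frozen=True)
class Prediction:
    """GP posterior at query locations, on both scales.

    ``f_star_mean``/``f_star_var`` are the log-space posterior mean
    (including m_GP) and variance of the latent field (nugget excluded);
    ``y_hat``/``sigma_y2`` are the corresponding log-normal mean and variance
    on the fluorescence scale.
    """

    f_star_mean: np.ndarray
    f_star_var: np.ndarray
    y_hat: np.ndarray
    sigma_y2: np.ndarray


class LogGPModel:
    """Log-Gaussian-process field model built from positive measurements.

    Parameters
    ----------
    y : array (n,)
        Positive fluorescence values (non-positive entries clipped to
        ``value_floor``).
    locations : array (n, 3)
        Local-frame positions (x, y, z) in metres.
    times : array (n,)
        Acquisition times, seconds since the mission epoch.
    hyperparams : LGPHyperparams
    value_floor : float
        Clipping floor applied before the log transform.

    Duplicate (location, time) rows are merged by averaging their values
    before the solve, protecting the conditioning of the covariance matrix.
    An empty model is allowed (pre-pilot state): it predicts the prior with
    ``m_GP = 0`` and variance ``sigma_c^2``, with a warning.
    """

    def __init__(
        self,
        y: np.ndarray,
        locations: np.ndarray,
        times: np.ndarray,
        hyperparams: LGPHyperparams | None = None,
        value_floor: float = DEFAULT_VALUE_FLOOR,
    ):
        self.hyperparams = hyperparams or LGPHyperparams()
        self.value_floor = value_floor
        y = np.atleast_1d(np.asarray(y, dtype=float))
        locations = np.asarray(locations, dtype=float).reshape(len(y), 3)
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if not (len(y) == len(locations) == len(times)):
            raise ValueError("y, locations and times must have equal length")
        st = np.column_stack([locations, times])
        if len(y):
            # merge exact duplicates of (x, y, z, tau) by averaging
            uniq, inv = np.unique(st, axis=0, return_inverse=True)
            if len(uniq) < len(st):
                sums = np.zeros(len(uniq))
                cnts = np.zeros(len(uniq))
                np.add.at(sums, inv, y)
                np.add.at(cnts, inv, 1.0)
                y = sums / cnts
                st = uniq
        self.S = st  # (n, 4) space-time training locations
        self.y_S = y
        if len(y):
            self.z_S, self.m_GP = log_transform(y, floor=value_floor)
        else:
            self.z_S = np.zeros(0)
            self.m_GP = 0.0

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        hyperparams: LGPHyperparams | None = None,
        columns: dict[str, str] | None = None,
        **kwargs,
    ) -> "LogGPModel":
        """Build from a DataFrame with columns x, y, z, time, value
        (override names via ``columns``)."""
        cols = {"x": "x", "y": "y", "z": "z", "time": "time", "value": "value"}
        cols.update(columns or {})
        missing = [c for c in cols.values() if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        return cls(
            df[cols["value"]].to_numpy(),
            df[[cols["x"], cols["y"], cols["z"]]].to_numpy(),
            df[cols["time"]].to_numpy(),
            hyperparams,
            **kwargs,
        )

    @classmethod
    def from_grid(
        cls,
        grid: GridState,
        hyperparams: LGPHyperparams | None = None,
        channel: int = 0,
        **kwargs,
    ) -> "LogGPModel":
        """Build from the occupied cells of a segmented grid (locations are
        cell centres, one training point per cell)."""
        locs, times, values, _ = grid.training_arrays()
        return cls(values[:, channel], locs, times, hyperparams, **kwargs)

    @property
    def n_train(self) -> int:
        return len(self.y_S)

    def fit(self) -> "LogGPResults":
        """Factorise the training covariance and return a results object.

        The training covariance ``K_{S,S} + sigma_n^2 I`` depends only on the
        (fixed) training space-time locations, so its Cholesky factor is
        computed once here; the prediction time ``tau_now`` enters only the
        cross-covariance, rebuilt per prediction.
        """
        hp = self.hyperparams
        if self.n_train == 0:
            warnings.warn(
                "fitting an empty model: predictions revert to the prior "
                "(m_GP = 0, variance sigma_c^2)",
                stacklevel=2,
            )
            return LogGPResults(self, None, np.zeros(0))
        K = kernel_matrix(self.S, self.S, hp)
        K[np.diag_indices_from(K)] += hp.sigma_n**2
        try:
            factor = cho_factor(K, lower=True)
        except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
            raise np.linalg.LinAlgError(
                f"training covariance not positive definite ({e}); check "
                "hyperparameters and duplicated points"
            ) from e
        alpha = cho_solve(factor, self.z_S)
        return LogGPResults(self, factor, alpha)


class LogGPResults:
    """Fitted log-GP: posterior prediction, diagnostics and summary."""

    def __init__(self, model: LogGPModel, factor, alpha: np.ndarray):
        self.model = model
        self._factor = factor
        self._alpha = alpha

    @property
    def m_GP(self) -> float:
        return self.model.m_GP

    @property
    def log_marginal_likelihood(self) -> float:
        """Gaussian log marginal likelihood of z_S under the kernel."""
        m = self.model
        if m.n_train == 0:
            return 0.0
        L = self._factor[0]
        return float(
            -0.5 * m.z_S @ self._alpha
            - np.sum(np.log(np.diag(L)))
            - 0.5 * m.n_train * np.log(2 * np.pi)
        )

    def predict(self, locations: np.ndarray, tau_now: float) -> Prediction:
        """Posterior at (n, 3) local positions, all evaluated at time tau_now.

        Returns the latent-field posterior (nugget excluded from the
        reported variance) on the log scale and, via the log-normal moment
        transform, on the fluorescence scale.
        """
        m = self.model
        hp = m.hyperparams
        locations = np.asarray(locations, dtype=float)
        single = locations.ndim == 1
        locations = np.atleast_2d(locations)
        S_star = np.column_stack(
            [locations, np.full(len(locations), float(tau_now))]
        )
        if m.n_train == 0:
            f_mean = np.full(len(locations), m.m_GP)
            f_var = np.full(len(locations), hp.sigma_c**2)
        else:
            K_star = kernel_matrix(S_star, m.S, hp)
            f_mean = K_star @ self._alpha + m.m_GP
            L = self._factor[0]
            # var = k(*,*) - || L^{-1} K_{S,*} ||^2, column-wise
            V = solve_triangular(L, K_star.T, lower=True)
            f_var = hp.sigma_c**2 - np.sum(V**2, axis=0)
            f_var = np.clip(f_var, 0.0, hp.sigma_c**2)
        y_hat, sigma_y2 = lognormal_moments(f_mean, f_var)
        if single:
            return Prediction(f_mean[0], f_var[0], y_hat[0], sigma_y2[0])
        return Prediction(f_mean, f_var, y_hat, sigma_y2)

    def predict_grid(self, cfg: VolumeConfig, tau_now: float) -> pd.DataFrame:
        """Posterior at every grid-cell centre; tidy frame for export/plots."""
        from .geometry import all_cell_centers

        centers = all_cell_centers(cfg)
        p = self.predict(centers, tau_now)
        return pd.DataFrame(
            {
                "x": centers[:, 0],
                "y": centers[:, 1],
                "z": centers[:, 2],
                "f_star_mean": p.f_star_mean,
                "f_star_var": p.f_star_var,
                "y_hat": p.y_hat,
                "sigma_y2": p.sigma_y2,
            }
        )

    def summary(self) -> str:
        m = self.model
        hp = m.hyperparams
        lines = [
            "Log-Gaussian-process field model",
            "=" * 40,
            f"training points        {m.n_train}",
            f"m_GP (log mean)        {m.m_GP: .6f}",
            f"M (x, y, z) [m]        {hp.M[0]:g}, {hp.M[1]:g}, {hp.M[2]:g}",
            f"M_tau [s]              {hp.M[3]:g}",
            f"sigma_c (process sd)   {hp.sigma_c:g}",
            f"sigma_n (nugget sd)    {hp.sigma_n:g}",
            f"log marginal lik.      {self.log_marginal_likelihood: .4f}",
        ]
        return "\n".join(lines)
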
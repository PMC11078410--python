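"""Geostatistical validation: semivariogram and distribution best-fit.

The on-board model's hyperparameters — horizontal de-correlation length,
process variance and nugget — can be checked against data with an empirical
semivariogram of the log values,

    gamma(h) = mean over pairs with |x_i - x_j| in the lag bin of
               1/2 (z_i - z_j)^2,

fitted with the spherical model

    gamma(h) = nugget + psill * (1.5 h/a - 0.5 (h/a)^3)   for h < a,
               nugget + psill                             for h >= a,

by least squares weighted by per-bin pair counts. Lags are horizontal-only:
vertical structure has far shorter scales and is treated separately, and
time is ignored for missions much shorter than the de-correlation time.

The log-normality assumption is checked by maximum-likelihood fitting of
candidate distributions (log-normal, gamma, beta, Burr XII, normal) and
ranking them by the sum of squared errors against a density-normalised
histogram, with the Akaike information criterion reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist


@dataclass
class Semivariogram:
    """Empirical semivariance per lag bin (NaN where a bin holds no pairs)."""

    bin_edges: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag": self.centers, "gamma": self.gamma, "n_pairs": self.counts}
        )


def empirical_variogram(
    values: np.ndarray,
    positions: np.ndarray,
    bin_edges: np.ndarray | None = None,
    subsample: float = 1.0,
    seed: int | None = None,
) -> Semivariogram:
    """Empirical semivariogram over horizontal lags.

    Parameters
    ----------
    values : (n,) log-scale values (consistent with the model's z units).
    positions : (n, 2) or (n, 3) positions; only the first two (horizontal)
        coordinates enter the lag distance.
    bin_edges : lag bin edges in metres; default 0-2000 m in 100 m bins.
    subsample : fraction of points randomly retained before pairing
        (variograms are O(n^2); field analyses typically subsample).
    seed : RNG seed for the subsample, making the estimate reproducible.
    """
    values = np.asarray(values, dtype=float)
    xy = np.asarray(positions, dtype=float)[:, :2]
    if len(values) != len(xy):
        raise ValueError("values and positions must have equal length")
    if bin_edges is None:
        bin_edges = np.arange(0.0, 2000.0 + 100.0, 100.0)
    bin_edges = np.asarray(bin_edges, dtype=float)

    if subsample < 1.0:
        rng = np.random.default_rng(seed)
        keep = rng.random(len(values)) < subsample
        values, xy = values[keep], xy[keep]
    if len(values) < 2:
        raise ValueError("need at least two points after subsampling")

    d = pdist(xy)
    sq = 0.5 * pdist(values[:, None], "sqeuclidean")
    which = np.digitize(d, bin_edges) - 1
    n_bins = len(bin_edges) - 1
    gamma = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        counts[b] = int(sel.sum())
        if counts[b]:
            gamma[b] = float(sq[sel].mean())
    return Semivariogram(bin_edges, gamma, counts)


@dataclass
class SphericalFit:
    """Spherical variogram model parameters (all >= 0).

    ``range_unidentifiable`` flags the degenerate pure-nugget case, where
    the partial sill is ~0 and the range carries no information.
    """

    nugget: float
    psill: float
    range_: float
    range_unidentifiable: bool = False

    def predict(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        hr = np.minimum(h / self.range_, 1.0)
        return self.nugget + self.psill * (1.5 * hr - 0.5 * hr**3)

    @property
    def sill(self) -> float:
        """Total sill, the plateau semivariance nugget + partial sill."""
        return self.nugget + self.psill


def spherical_model(h, nugget, psill, range_):
    hr = np.minimum(np.asarray(h, float) / range_, 1.0)
    return nugget + psill * (1.5 * hr - 0.5 * hr**3)


def fit_spherical(vg: Semivariogram) -> SphericalFit:
    """Weighted least-squares spherical fit (weights = per-bin pair counts)."""
    ok = ~np.isnan(vg.gamma) & (vg.counts > 0)
    if ok.sum() < 3:
        raise ValueError("need at least three non-empty lag bins")
    h = vg.centers[ok]
    g = vg.gamma[ok]
    w = vg.counts[ok].astype(float)

    g_max = float(g.max())
    scale = g_max if g_max > 0 else 1.0
    p0 = [max(float(g[0]), 1e-6 * scale), max(g_max - float(g[0]), 1e-6 * scale),
          float(h.max()) / 2]
    try:
        popt, _ = optimize.curve_fit(
            spherical_model,
            h,
            g,
            p0=p0,
            sigma=1.0 / np.sqrt(w),
            bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, 100 * float(h.max())]),
            maxfev=20_000,
        )
    except RuntimeError as e:
        raise RuntimeError(
            f"spherical variogram fit did not converge: {e}; "
            f"bins={ok.sum()}, gamma range=({g.min():.3g}, {g.max():.3g})"
        ) from e
    nugget, psill, rng_ = (float(p) for p in popt)
    degenerate = psill < 1e-3 * max(nugget, 1e-12)
    return SphericalFit(nugget, psill, rng_, range_unidentifiable=degenerate)


# ---------------------------------------------------------------------------
# Distribution best-fit
# ---------------------------------------------------------------------------

#: Candidate distributions and how they are fitted. Positive-support
#: candidates are fitted with location pinned at 0; the beta candidate is
#: fitted on values rescaled to (0, 1) with the Jacobian folded into its
#: likelihood and density.
DEFAULT_CANDIDATES = ("lognormal", "gamma", "beta", "burr", "normal")

_SCIPY_DISTS = {
    "lognormal": stats.lognorm,
    "gamma": stats.gamma,
    "burr": stats.burr12,
    "normal": stats.norm,
}


@dataclass
class DistFitReport:
    """Per-candidate MLE parameters, histogram SSE and AIC, sorted by SSE."""

    table: pd.DataFrame
    histogram: tuple[np.ndarray, np.ndarray]  # (density, bin_edges)

    @property
    def best(self) -> str:
        return str(self.table.index[0])

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.6g}")


def _fit_candidate(name: str, x: np.ndarray):
    """Returns (params, cdf callable on original scale, n_params, loglik)."""
    n = len(x)
    if name == "beta":
        lo, hi = x.min(), x.max()
        span = (hi - lo) * 1.02
        a0 = lo - 0.01 * (hi - lo)
        u = (x - a0) / span
        pa, pb, loc, scl = stats.beta.fit(u, floc=0, fscale=1)
        loglik = float(np.sum(stats.beta.logpdf(u, pa, pb)) - n * np.log(span))
        cdf = lambda v: stats.beta.cdf((v - a0) / span, pa, pb)
        return (pa, pb), cdf, 2, loglik
    dist = _SCIPY_DISTS[name]
    if name == "normal":
        params = dist.fit(x)
    else:
        params = dist.fit(x, floc=0)
    loglik = float(np.sum(dist.logpdf(x, *params)))
    cdf = lambda v: dist.cdf(v, *params)
    # count only free parameters (loc pinned at 0 is not estimated)
    n_params = len(params) - (0 if name == "normal" else 1)
    return params, cdf, n_params, loglik


def best_fit(
    values: np.ndarray,
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES,
    n_bins: int = 50,
) -> DistFitReport:
    """Rank candidate distributions for positive data by histogram SSE.

    Each candidate is fitted by maximum likelihood; SSE is computed between
    its bin-averaged density (CDF increment over bin width, the quantity a
    density-normalised histogram bar estimates) and a ``n_bins`` equal-width
    histogram; AIC = 2 k - 2 ln L. Candidates whose fit fails are flagged
    (NaN scores) and the others still reported.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 30:
        raise ValueError("need at least 30 values for a meaningful fit")
    if np.any(x <= 0):
        raise ValueError("best_fit expects positive values")

    hist, edges = np.histogram(x, bins=n_bins, density=True)
    widths = np.diff(edges)

    rows = {}
    for name in candidates:
        try:
            params, cdf, k, loglik = _fit_candidate(name, x)
            dens = np.diff(cdf(edges)) / widths
            sse = float(np.sum((dens - hist) ** 2))
            aic = 2 * k - 2 * loglik
            rows[name] = {
                "sse": sse,
                "aic": aic,
                "n_params": k,
                "loglik": loglik,
                "params": tuple(round(float(p), 6) for p in params),
                "failed": False,
            }
        except Exception as e:  # fit failure: flag, keep going
            rows[name] = {
                "sse": np.nan,
                "aic": np.nan,
                "n_params": np.nan,
                "loglik": np.nan,
                "params": (),
                "failed": True,
                "error": str(e),
            }
    table = pd.DataFrame(rows).T
    table = table.sort_values("sse", na_position="last")
    return DistFitReport(table, (hist, edges))
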
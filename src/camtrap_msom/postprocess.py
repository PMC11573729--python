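"""Derived analyses on the fitted occupancy model: site-level richness,
richness-vs-covariate regression, species accumulation, and diel
activity overlap between two groups (e.g. humans vs wildlife).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import i0e, ive

from .covariates import DesignMatrix
from .msom import PosteriorSamples

__all__ = [
    "SiteRichness",
    "site_richness",
    "richness_regression",
    "accumulation_curve",
    "plot_accumulation",
    "activity_overlap",
]


@dataclass
class SiteRichness:
    """Posterior draws and means of per-site richness N_i = sum_k w_k z_ik."""

    sites: list
    draws: np.ndarray  # (n_total_draws, I)

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "site": self.sites,
            "richness_mean": self.mean,
            "richness_sd": self.draws.std(axis=0, ddof=1),
            "q2.5": np.percentile(self.draws, 2.5, axis=0),
            "q97.5": np.percentile(self.draws, 97.5, axis=0),
        })


def site_richness(samples: PosteriorSamples) -> SiteRichness:
    """Extract per-site richness draws from the fitted model."""
    return SiteRichness(sites=list(range(samples.data.n_sites)),
                        draws=samples.flat("Ni").astype(float))


def richness_regression(mean_n: np.ndarray, design: DesignMatrix | pd.DataFrame
                        ) -> pd.DataFrame:
    """Ordinary least squares of posterior-mean site richness on the
    standardized covariates, with intercept.

    Returns one row per term: beta, se, 95% CI bounds, t, two-sided p,
    and the residual degrees of freedom.
    """
    if isinstance(design, DesignMatrix):
        Xdf = design.to_frame().reset_index(drop=True)
    else:
        Xdf = pd.DataFrame(design).reset_index(drop=True)
    y = np.asarray(mean_n, dtype=float)
    if len(y) <= Xdf.shape[1] + 1:
        raise ValueError("need more sites than regression terms")
    X = sm.add_constant(Xdf)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = [c for c in Xdf.columns
                     if np.linalg.matrix_rank(
                         X.drop(columns=[c]).to_numpy()) == rank]
        raise ValueError(f"design matrix is rank deficient; "
                         f"collinear column(s): {collinear}")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    out = pd.DataFrame({
        "term": X.columns,
        "beta": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "ci_lower": ci[0].to_numpy(),
        "ci_upper": ci[1].to_numpy(),
        "t": fit.tvalues.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })
    out["df_resid"] = int(fit.df_resid)
    return out


def accumulation_curve(records: pd.DataFrame,
                       start: pd.Timestamp | None = None) -> pd.DataFrame:
    """Cumulative count of distinct species detected by each survey day,
    pooled across sites (wildlife records only).

    ``start`` anchors day 1 (default: the first record's date).
    """
    wl = records.loc[records["kind"].eq("wildlife")]
    if wl.empty:
        raise ValueError("no wildlife records")
    day0 = (pd.Timestamp(start).normalize() if start is not None
            else wl["timestamp"].min().normalize())
    day = (wl["timestamp"].dt.normalize() - day0).dt.days + 1
    first_day = wl.assign(day=day).groupby("species")["day"].min()
    horizon = int(day.max())
    cum = np.zeros(horizon, dtype=int)
    for d in first_day:
        cum[max(int(d), 1) - 1:] += 1
    return pd.DataFrame({"occasion": np.arange(1, horizon + 1),
                         "cumulative_species": cum})


def plot_accumulation(curve: pd.DataFrame, n_mean: float | None = None,
                      n_sd: float | None = None, path=None):
    """Plot the accumulation curve with the posterior-mean richness line
    (and +/- 1 posterior sd band) for visual comparison."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(curve["occasion"], curve["cumulative_species"], where="post",
            color="black")
    if n_mean is not None:
        ax.axhline(n_mean, color="tab:blue", label="estimated richness")
        if n_sd is not None:
            ax.axhspan(n_mean - n_sd, n_mean + n_sd, color="tab:blue",
                       alpha=0.15)
        ax.legend()
    ax.set_xlabel("survey occasion (day)")
    ax.set_ylabel("cumulative species detected")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# diel activity overlap


def _to_radians(times) -> np.ndarray:
    """Clock times to angles: hours (mod 24) -> [0, 2pi)."""
    t = pd.Series(times)
    if pd.api.types.is_datetime64_any_dtype(t):
        hours = (t.dt.hour + t.dt.minute / 60.0 + t.dt.second / 3600.0)
    else:
        hours = t.astype(float)
    return (np.asarray(hours, dtype=float) % 24.0) * (2.0 * np.pi / 24.0)


def _kappa_mle(theta: np.ndarray) -> float:
    """Von Mises concentration from the mean resultant length
    (Best & Fisher approximation)."""
    r = float(np.hypot(np.mean(np.sin(theta)), np.mean(np.cos(theta))))
    r = min(r, 1.0 - 1e-10)
    if r < 0.53:
        return 2 * r + r ** 3 + 5 * r ** 5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r ** 3 - 4 * r ** 2 + 3 * r)


def _kernel_concentration(theta: np.ndarray, adjust: float = 1.0) -> float:
    """Plug-in smoothing concentration for the von Mises kernel
    (Taylor's circular bandwidth rule)."""
    kappa = max(_kappa_mle(theta), 1e-6)
    n = theta.size
    # evaluated in log space with scaled Bessels so that very
    # concentrated samples stay finite
    log_num = (np.log(3.0 * n) + 2.0 * np.log(kappa)
               + np.log(ive(2, 2.0 * kappa)) + 2.0 * kappa)
    log_den = (np.log(4.0 * np.sqrt(np.pi))
               + 2.0 * (np.log(ive(1, kappa)) + kappa))
    nu = np.exp(0.4 * (log_num - log_den))
    if not np.isfinite(nu):
        nu = kappa * n ** (2.0 / 5.0)
    return float(nu) * adjust


def _vm_kde(grid: np.ndarray, theta: np.ndarray, nu: float) -> np.ndarray:
    """Von Mises kernel density on ``grid`` (exponentially scaled Bessel
    keeps large concentrations stable)."""
    diff = np.cos(grid[:, None] - theta[None, :]) - 1.0
    dens = np.exp(nu * diff).mean(axis=1) / (2 * np.pi * i0e(nu))
    return dens


def activity_overlap(times_a, times_b, n_grid: int = 512,
                     adjust: float = 1.0) -> float:
    """Coefficient of overlap Delta-hat between two diel activity densities.

    Each sample of clock times is smoothed with a circular von Mises
    kernel (plug-in concentration); Delta-hat-1 = integral of
    min(f, g) over the day, evaluated by the trapezoid rule on
    ``n_grid`` points and clipped to [0, 1].
    """
    a = _to_radians(times_a)
    b = _to_radians(times_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations in each sample")
    grid = np.linspace(0.0, 2 * np.pi, n_grid + 1)
    fa = _vm_kde(grid, a, _kernel_concentration(a, adjust))
    fb = _vm_kde(grid, b, _kernel_concentration(b, adjust))
    dhat = np.trapezoid(np.minimum(fa, fb), grid)
    return float(np.clip(dhat, 0.0, 1.0))
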
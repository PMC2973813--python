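"""Neutral-mode analysis: Ks density, correlations, and the strength-Ks fit.

Buffering strength is the (negative) interaction score; under neutral decay
it regresses linearly on Ks among pairs below the saturation threshold
(Ks <= 2), and the Ks-strength association survives controlling for Ka
while the Ka-strength association does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

KS_SATURATION = 2.0
MODE_PROMINENCE_FRACTION = 0.01  # of max density


class EvolutionError(ValueError):
    pass


class DegenerateDensityError(EvolutionError):
    pass


# ---------------------------------------------------------------------------
# Kernel density estimation
# ---------------------------------------------------------------------------

@dataclass
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    modes: np.ndarray  # grid locations of detected local maxima

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def silverman_bandwidth(values: np.ndarray) -> float:
    """0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    sd = float(np.std(values, ddof=1))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    if spread <= 0:
        raise DegenerateDensityError("all values identical; bandwidth undefined")
    return 0.9 * spread * len(values) ** (-0.2)


def gaussian_kde(
    values,
    bandwidth: float | None = None,
    grid_size: int = 512,
) -> DensityEstimate:
    """Gaussian-window density on an even grid spanning [min-3h, max+3h].

    Modes are strict local maxima of the gridded density, with a minimum
    prominence of 1% of the peak density to suppress noise modes.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 5:
        raise EvolutionError("need at least 5 finite values")
    h = bandwidth if bandwidth is not None else silverman_bandwidth(x)
    if h <= 0:
        raise DegenerateDensityError("non-positive bandwidth")
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    z = (grid[:, None] - x[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (len(x) * h * math.sqrt(2 * math.pi))
    peaks, _ = signal.find_peaks(density, prominence=MODE_PROMINENCE_FRACTION * density.max())
    return DensityEstimate(grid=grid, density=density, bandwidth=h, modes=grid[peaks])


def plot_density(estimate: DensityEstimate, path: str, xlabel: str = "Ks") -> None:
    """Write a density plot (PNG/SVG chosen by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(estimate.grid, estimate.density, lw=1.5)
    for m in estimate.modes:
        ax.axvline(m, ls="--", color="grey", lw=0.8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    controlled_for: str | None = None


def pearson_test(x, y) -> CorrelationResult:
    """Pearson r with a two-sided t-based p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise EvolutionError("length mismatch")
    if len(x) < 3:
        raise EvolutionError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise EvolutionError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise EvolutionError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x))


def partial_correlation(x, y, z, controlled_for: str | None = None) -> CorrelationResult:
    """First-order partial correlation of x and y controlling for z.

    r_xy.z = (r_xy - r_xz*r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)); the two-sided
    p-value uses the t transform with n-3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape):
        raise EvolutionError("length mismatch")
    n = len(x)
    if n < 4:
        raise EvolutionError("need n >= 4 for a partial correlation")
    r_xy = pearson_test(x, y).r
    r_xz = pearson_test(x, z).r
    r_yz = pearson_test(y, z).r
    denom_sq = (1 - r_xz**2) * (1 - r_yz**2)
    if denom_sq <= 1e-12:
        raise EvolutionError("degenerate: a control correlation is +/-1")
    r = (r_xy - r_xz * r_yz) / math.sqrt(denom_sq)
    r = max(-1.0, min(1.0, r))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), df)
    return CorrelationResult(r=r, p=float(p), n=n, controlled_for=controlled_for)


# ---------------------------------------------------------------------------
# Regression and report
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def strength_ks_regression(strength, ks, ks_max: float = KS_SATURATION) -> RegressionFit:
    """OLS of buffering strength on Ks over pairs with Ks <= ks_max."""
    strength = np.asarray(strength, dtype=float)
    ks = np.asarray(ks, dtype=float)
    if strength.shape != ks.shape:
        raise EvolutionError("length mismatch")
    mask = np.isfinite(strength) & np.isfinite(ks) & (ks <= ks_max)
    if mask.sum() < 3:
        raise EvolutionError(
            f"fewer than 3 pairs remain after the Ks <= {ks_max} saturation filter"
        )
    fit = stats.linregress(ks[mask], strength[mask])
    return RegressionFit(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r=float(fit.rvalue), p=float(fit.pvalue), n=int(mask.sum()),
    )


def neutral_mode_report(
    strength,
    ka,
    ks,
    ks_max: float = KS_SATURATION,
    bandwidth: float | None = None,
) -> dict:
    """Assemble the neutral-mode panel: both partial correlations, the
    strength-on-Ks regression (Ks <= ks_max only), and the Ks density modes
    (over all supplied Ks, including saturated pairs)."""
    strength = np.asarray(strength, dtype=float)
    ka = np.asarray(ka, dtype=float)
    ks = np.asarray(ks, dtype=float)
    if not (strength.shape == ka.shape == ks.shape):
        raise EvolutionError("length mismatch")
    if len(strength) == 0:
        raise EvolutionError("empty input")
    mask = np.isfinite(strength) & np.isfinite(ka) & np.isfinite(ks) & (ks <= ks_max)
    n_used = int(mask.sum())
    report: dict = {
        "n_input": int(len(strength)),
        "n_used": n_used,
        "n_excluded": int(len(strength) - n_used),
        "ks_max": ks_max,
    }
    pc_ks = partial_correlation(ks[mask], strength[mask], ka[mask], controlled_for="ka")
    pc_ka = partial_correlation(ka[mask], strength[mask], ks[mask], controlled_for="ks")
    report["partial_correlations"] = {
        "ks_strength_given_ka": {"r": pc_ks.r, "p": pc_ks.p, "n": pc_ks.n},
        "ka_strength_given_ks": {"r": pc_ka.r, "p": pc_ka.p, "n": pc_ka.n},
    }
    fit = strength_ks_regression(strength, ks, ks_max=ks_max)
    report["regression"] = {
        "slope": fit.slope, "intercept": fit.intercept,
        "r": fit.r, "p": fit.p, "n": fit.n,
    }
    finite_ks = ks[np.isfinite(ks)]
    if len(finite_ks) >= 5:
        kde = gaussian_kde(finite_ks, bandwidth=bandwidth)
        report["ks_density"] = {
            "bandwidth": kde.bandwidth,
            "modes": [float(m) for m in kde.modes],
            "n": int(len(finite_ks)),
        }
    else:
        report["ks_density"] = None
    return report
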
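"""Spike-train validation statistics.

The pipeline used to establish simulation correctness: per-neuron firing
rates, the coefficient of variation of inter-spike intervals (CV ISI),
pairwise Pearson correlation of binned spike trains, Gaussian kernel density
estimation with Silverman's-rule bandwidth, and the Kullback-Leibler
divergence between smoothed distributions.  Two simulators (or two seeds)
are compared by computing these distributions per population and measuring
the KL divergence of matched run pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SpikeTrainSet", "DensityEstimate", "firing_rates", "cv_isi",
           "cv_isi_distribution", "binned_pearson", "silverman_bandwidth",
           "kde", "kl_divergence", "seed_pair_protocol",
           "PairProtocolResult", "population_summary"]


@dataclass
class SpikeTrainSet:
    """Per-population spike trains within an observation window.

    ``trains`` maps population name -> {neuron id -> sorted spike times (ms)}.
    """

    trains: dict
    t0: float
    t1: float

    @classmethod
    def from_events(cls, senders, times, window, populations):
        """Group raw (sender, time) events by population id ranges.

        ``populations`` maps name -> iterable of node ids.  Neurons without
        spikes are included with empty trains.  Events outside the window
        are dropped (transient removal).
        """
        t0, t1 = window
        senders = np.asarray(senders)
        times = np.asarray(times)
        keep = (times >= t0) & (times <= t1)
        senders, times = senders[keep], times[keep]
        order = np.argsort(senders, kind="stable")
        senders, times = senders[order], times[order]
        out = {}
        for name, ids in populations.items():
            ids = np.asarray(ids)
            lo = np.searchsorted(senders, ids, side="left")
            hi = np.searchsorted(senders, ids, side="right")
            out[name] = {int(i): np.sort(times[a:b])
                         for i, a, b in zip(ids, lo, hi)}
        return cls(out, t0, t1)

    @property
    def window_ms(self):
        return self.t1 - self.t0


def firing_rates(trains, window):
    """Per-neuron firing rates in Hz (spike count / window length).

    ``trains``: {neuron id -> spike time array}; silent neurons count as
    0 Hz.  ``window`` is (t0, t1) in ms.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window length must be positive")
    w_s = (t1 - t0) / 1000.0
    return np.array([np.count_nonzero((t >= t0) & (t <= t1)) / w_s
                     for t in trains.values()])


def cv_isi(train):
    """Coefficient of variation of inter-spike intervals.

    Population (ddof=0) standard deviation over mean.  Undefined (NaN) for
    trains with fewer than 3 spikes, which are excluded from distributions
    rather than counted as zero.
    """
    train = np.asarray(train, dtype=float)
    if train.size < 3:
        return np.nan
    isi = np.diff(np.sort(train))
    m = isi.mean()
    if m == 0:
        return np.nan
    return isi.std() / m


def cv_isi_distribution(trains):
    vals = np.array([cv_isi(t) for t in trains.values()])
    return vals[~np.isnan(vals)]


def binned_pearson(trains, window, n_neurons=200, bin_ms=2.0, seed=0):
    """Off-diagonal pairwise Pearson correlations of binned spike trains.

    A seeded uniform subsample of ``n_neurons`` neurons is taken without
    replacement; their trains are binned into spike counts per ``bin_ms``
    bin and the correlation matrix C[i,j] = <b_i - mu_i, b_j - mu_j> /
    sqrt(<b_i - mu_i, b_i - mu_i> <b_j - mu_j, b_j - mu_j>) is computed.
    All-zero (constant) trains have undefined correlations and are excluded
    with a warning.  Returns the off-diagonal elements.
    """
    t0, t1 = window
    ids = list(trains.keys())
    rng = np.random.default_rng(seed)
    if len(ids) > n_neurons:
        pick = rng.choice(len(ids), size=n_neurons, replace=False)
        ids = [ids[i] for i in sorted(pick)]
    n_bins = int(np.floor((t1 - t0) / bin_ms))
    edges = t0 + np.arange(n_bins + 1) * bin_ms
    binned = np.stack([np.histogram(trains[i], bins=edges)[0] for i in ids])
    active = binned.std(axis=1) > 0
    if not active.all():
        warnings.warn(f"{np.count_nonzero(~active)} constant spike trains "
                      "excluded from correlation")
        binned = binned[active]
    if binned.shape[0] < 2:
        return np.zeros(0)
    c = np.corrcoef(binned)
    off = ~np.eye(c.shape[0], dtype=bool)
    return c[off]


@dataclass
class DensityEstimate:
    """KDE-smoothed density on a sampling grid, unit trapezoidal integral."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    @property
    def integral(self):
        return float(np.trapezoid(self.density, self.grid))


def silverman_bandwidth(sample):
    """Silverman's rule: b = 0.9 min(sigma, IQR/1.349) N^(-1/5)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples for a bandwidth")
    sigma = x.std(ddof=1)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    spread = min(sigma, iqr / 1.349) if iqr > 0 else sigma
    return 0.9 * spread * x.size ** (-0.2)


def kde(sample, grid=None, bandwidth=None, n_grid=512, pad_bw=4.0,
        min_bandwidth=1e-3):
    """Gaussian kernel density estimate with Silverman's-rule bandwidth.

    Each sample point contributes a Gaussian of integral 1/N, so the summed
    density integrates to one.  Degenerate samples (zero spread) fall back
    to ``min_bandwidth`` with a warning.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples for a KDE")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(x)
    if bandwidth <= 0:
        warnings.warn("zero sample spread; falling back to the minimum "
                      f"bandwidth {min_bandwidth}")
        bandwidth = min_bandwidth
    if grid is None:
        lo = x.min() - pad_bw * bandwidth
        hi = x.max() + pad_bw * bandwidth
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=1) \
        / (x.size * bandwidth * np.sqrt(2 * np.pi))
    return DensityEstimate(grid, dens, float(bandwidth))


def kl_divergence(p1: DensityEstimate, p2: DensityEstimate, eps=1e-12):
    """KL divergence D(p1 || p2) = int p1 log(p1/p2) >= 0 on a shared grid.

    The second density is floored at ``eps`` before renormalization to avoid
    division by zero in regions p2 does not cover.
    """
    if p1.grid.shape != p2.grid.shape or not np.allclose(p1.grid, p2.grid):
        raise ValueError("densities must share the same grid")
    g = p1.grid
    a = np.maximum(p1.density, 0.0)
    b = np.maximum(p2.density, eps)
    a = a / np.trapezoid(a, g)
    b = b / np.trapezoid(b, g)
    integrand = np.where(a > 0, a * np.log(np.maximum(a, eps) / b), 0.0)
    return float(np.trapezoid(integrand, g))


@dataclass
class PairProtocolResult:
    cross_mean: float
    cross_std: float
    baseline_mean: float
    baseline_std: float
    cross_values: np.ndarray
    baseline_values: np.ndarray

    def compatible(self, n_sigma=3.0):
        """Cross-condition divergence within the seed-to-seed band."""
        band = self.baseline_mean + n_sigma * max(self.baseline_std,
                                                  self.cross_std, 1e-12)
        return self.cross_mean <= band


def _pair_kl(sa, sb):
    both = np.concatenate((sa, sb))
    ba = silverman_bandwidth(sa)
    bb = silverman_bandwidth(sb)
    pad = 4 * max(ba, bb, 1e-12)
    grid = np.linspace(both.min() - pad, both.max() + pad, 512)
    return kl_divergence(kde(sa, grid=grid), kde(sb, grid=grid))


def seed_pair_protocol(runs_a, runs_b, statistic=None):
    """Seed-pairing comparison of two run ensembles.

    ``runs_a``/``runs_b`` are lists of runs from two conditions (e.g., two
    backends), each run reduced by ``statistic`` (default: identity; the run
    is already a 1-D sample such as per-neuron rates).  Matched cross pairs
    (a_i, b_i) measure the between-condition divergence; within-condition
    pairs (a_i, a_{i+1 mod n}) give the seed-to-seed baseline band.
    """
    stat = statistic or (lambda r: np.asarray(r, dtype=float))
    a = [stat(r) for r in runs_a]
    b = [stat(r) for r in runs_b]
    if len(a) < 2 or len(b) < 1:
        raise ValueError("need at least two reference runs and one test run")
    if len(a) != len(b):
        warnings.warn("unequal run counts; truncating to the minimum")
    n = min(len(a), len(b))
    cross = np.array([_pair_kl(a[i], b[i]) for i in range(n)])
    base = np.array([_pair_kl(a[i], a[(i + 1) % len(a)])
                     for i in range(len(a))])
    return PairProtocolResult(float(cross.mean()), float(cross.std()),
                              float(base.mean()), float(base.std()),
                              cross, base)


def population_summary(trains, window, corr_seed=0):
    """Mean rate, mean CV ISI, and mean pairwise correlation of one population."""
    rates = firing_rates(trains, window)
    cvs = cv_isi_distribution(trains)
    corr = binned_pearson(trains, window, seed=corr_seed) \
        if len(trains) >= 2 else np.zeros(0)
    return {
        "n_neurons": len(trains),
        "mean_rate_hz": float(rates.mean()) if rates.size else 0.0,
        "mean_cv_isi": float(cvs.mean()) if cvs.size else float("nan"),
        "mean_pairwise_correlation":
            float(corr.mean()) if corr.size else float("nan"),
    }
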
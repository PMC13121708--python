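"""Partition droplets into subpopulations via the red reference channel.

The red dye is carried by the phage-side solution, so the red peak encodes
the mixing fraction ``alpha`` and the red pulse width encodes droplet size.
This module provides:

* discrete alpha-group recovery (1-D Gaussian mixture on red peaks),
* continuous alpha binning with a linear red -> alpha calibration,
* size-mode separation on red width with coalescence-outlier rejection,
* pulse detection turning a raw two-channel trace into an event table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.mixture import GaussianMixture

from .simulate import Trace

__all__ = [
    "PopulationAssignment",
    "AlphaCalibration",
    "RedPeakGrouper",
    "SizeModeGrouper",
    "AlphaBinner",
    "find_discrete_groups",
    "bin_continuous_alpha",
    "find_size_modes",
    "detect_droplets",
]


@dataclass
class PopulationAssignment:
    """Per-droplet group labels plus per-group summaries.

    ``labels`` is -1 for discarded droplets (outside calibration range,
    dropped bin, or flagged coalesced); ``groups`` has one row per retained
    group with columns n, mean_red_peak, mean_red_width and, where defined,
    alpha or volume proxies.
    """

    labels: np.ndarray
    coalesced: np.ndarray
    groups: pd.DataFrame
    discarded_fraction: float


@dataclass(frozen=True)
class AlphaCalibration:
    """Linear red-peak -> alpha map anchored at two externally measured points.

    The endpoints (typically the minimum and maximum alpha measured by
    microscopy) define ``alpha = intercept + slope * red``.  With
    ``red_encodes='bacteria'`` the red dye sits in the bacteria-side solution
    and the map yields ``1 - alpha`` instead.
    """

    red_low: float
    alpha_min: float
    red_high: float
    alpha_max: float
    red_encodes: str = "phage"

    def __post_init__(self) -> None:
        if self.red_high <= self.red_low:
            raise ValueError("red_high must exceed red_low")
        if not 0.0 <= self.alpha_min < self.alpha_max <= 1.0:
            raise ValueError("need 0 <= alpha_min < alpha_max <= 1")
        if self.red_encodes not in ("phage", "bacteria"):
            raise ValueError("red_encodes must be 'phage' or 'bacteria'")

    @property
    def slope(self) -> float:
        return (self.alpha_max - self.alpha_min) / (self.red_high - self.red_low)

    @property
    def intercept(self) -> float:
        return self.alpha_min - self.slope * self.red_low

    def alpha_of(self, red_peak) -> np.ndarray:
        """Mixing fraction(s) for red peak value(s)."""
        a = self.intercept + self.slope * np.asarray(red_peak, dtype=float)
        if self.red_encodes == "bacteria":
            a = 1.0 - a
        return a


class _Mixture1D(BaseEstimator, ClusterMixin):
    """Shared 1-D Gaussian-mixture grouping with mean-ordered labels."""

    def __init__(self, n_groups: int = 2, random_state: int = 0) -> None:
        self.n_groups = n_groups
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if np.ptp(x) == 0:
            raise ValueError("degenerate signals: all values identical")
        qs = (np.arange(self.n_groups) + 0.5) / self.n_groups
        gmm = GaussianMixture(
            n_components=self.n_groups,
            covariance_type="diag",
            means_init=np.quantile(x, qs).reshape(-1, 1),
            weights_init=np.full(self.n_groups, 1.0 / self.n_groups),
            random_state=self.random_state,
            n_init=1,
            reg_covar=1e-10 * max(np.var(x), 1e-30),
            max_iter=500,
        )
        gmm.fit(x[:, None])
        order = np.argsort(gmm.means_.ravel(), kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(order.size)
        self.means_ = gmm.means_.ravel()[order]
        self.sds_ = np.sqrt(gmm.covariances_.reshape(-1))[order]
        self.weights_ = gmm.weights_[order]
        self.posteriors_ = gmm.predict_proba(x[:, None])[:, order]
        self.labels_ = rank[gmm.predict(x[:, None])].astype(np.int64)
        return self


class RedPeakGrouper(_Mixture1D):
    """Recover discrete mixing-fraction subpopulations from red peaks.

    Groups are ordered by mean red signal ascending; droplets whose
    max-posterior probability falls below ``posterior_floor`` (if set) are
    discarded (label -1).
    """

    def __init__(self, n_groups: int = 2, random_state: int = 0,
                 posterior_floor: float | None = None) -> None:
        super().__init__(n_groups=n_groups, random_state=random_state)
        self.posterior_floor = posterior_floor

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if x.size < 50 * self.n_groups:
            raise ValueError(
                f"need >= {50 * self.n_groups} droplets for {self.n_groups} groups"
            )
        super().fit(x)
        if self.posterior_floor is not None:
            top = self.posteriors_.max(axis=1)
            self.labels_ = np.where(top >= self.posterior_floor, self.labels_, -1)
        return self


class SizeModeGrouper(_Mixture1D):
    """Separate droplet size modes on red-signal width; flag coalesced outliers.

    Widths beyond ``coalescence_z`` SDs above the largest legitimate mode are
    flagged coalesced (label -1, ``coalesced_`` True) and must be excluded
    from downstream positive-fraction statistics.
    """

    def __init__(self, n_modes: int = 2, coalescence_z: float = 4.0,
                 random_state: int = 0) -> None:
        super().__init__(n_groups=n_modes, random_state=random_state)
        self.n_modes = n_modes
        self.coalescence_z = coalescence_z

    def fit(self, X, y=None):
        if self.n_modes not in (1, 2):
            raise ValueError("n_modes must be 1 or 2")
        self.n_groups = self.n_modes
        x = np.asarray(X, dtype=float).ravel()
        super().fit(x)
        cut = self.means_[-1] + self.coalescence_z * self.sds_[-1]
        self.coalesced_ = x > cut
        self.labels_ = np.where(self.coalesced_, -1, self.labels_)
        return self


def _summarize(labels, red_peaks, red_widths, extra: dict | None = None) -> pd.DataFrame:
    rows = []
    for g in sorted(set(labels[labels >= 0])):
        m = labels == g
        row = {
            "group": int(g),
            "n": int(m.sum()),
            "mean_red_peak": float(np.mean(red_peaks[m])),
            "mean_red_width": float(np.mean(red_widths[m])),
        }
        if extra:
            for key, values in extra.items():
                row[key] = values[g]
        rows.append(row)
    return pd.DataFrame(rows)


def find_discrete_groups(
    red_peaks, n_groups: int, seed: int = 0,
    red_widths=None, posterior_floor: float | None = None,
) -> PopulationAssignment:
    """Cluster red peaks into ``n_groups`` discrete alpha subpopulations."""
    red_peaks = np.asarray(red_peaks, dtype=float).ravel()
    red_widths = (np.zeros_like(red_peaks) if red_widths is None
                  else np.asarray(red_widths, dtype=float).ravel())
    grouper = RedPeakGrouper(n_groups=n_groups, random_state=seed,
                             posterior_floor=posterior_floor).fit(red_peaks)
    labels = grouper.labels_
    groups = _summarize(labels, red_peaks, red_widths)
    return PopulationAssignment(
        labels=labels,
        coalesced=np.zeros(red_peaks.size, dtype=bool),
        groups=groups,
        discarded_fraction=float(np.mean(labels < 0)),
    )


class AlphaBinner(BaseEstimator):
    """Equal-width red-peak binning with a linear alpha calibration.

    Transform-shaped: :meth:`fit` freezes the bin edges from the calibration
    range, :meth:`transform` maps droplets to bin labels.  Droplets outside
    the calibration range are discarded, bins with fewer than
    ``min_bin_count`` droplets are dropped; each retained bin is assigned the
    alpha of its mean red peak.
    """

    def __init__(self, calibration: AlphaCalibration, n_bins: int = 300,
                 min_bin_count: int = 50) -> None:
        self.calibration = calibration
        self.n_bins = n_bins
        self.min_bin_count = min_bin_count

    def fit(self, X=None, y=None):
        if self.n_bins < 10:
            raise ValueError("n_bins must be >= 10")
        cal = self.calibration
        self.edges_ = np.linspace(cal.red_low, cal.red_high, self.n_bins + 1)
        return self

    def transform(self, X) -> PopulationAssignment:
        red = np.asarray(X, dtype=float).ravel()
        cal = self.calibration
        in_range = (red >= cal.red_low) & (red <= cal.red_high)
        if not in_range.any():
            raise ValueError("no droplets inside the calibration range")
        raw = np.clip(
            np.searchsorted(self.edges_, red, side="right") - 1, 0, self.n_bins - 1
        )
        labels = np.where(in_range, raw, -1)
        counts = np.bincount(labels[labels >= 0], minlength=self.n_bins)
        keep = counts >= self.min_bin_count
        labels = np.where((labels >= 0) & keep[np.clip(labels, 0, None)], labels, -1)
        rows = []
        for g in np.nonzero(keep)[0]:
            m = labels == g
            mean_red = float(np.mean(red[m]))
            rows.append({
                "group": int(g),
                "n": int(m.sum()),
                "mean_red_peak": mean_red,
                "mean_red_width": np.nan,
                "alpha": float(cal.alpha_of(mean_red)),
            })
        groups = pd.DataFrame(rows)
        return PopulationAssignment(
            labels=labels,
            coalesced=np.zeros(red.size, dtype=bool),
            groups=groups,
            discarded_fraction=float(np.mean(labels < 0)),
        )


def bin_continuous_alpha(
    red_peaks, n_bins: int, min_bin_count: int, cal: AlphaCalibration
) -> PopulationAssignment:
    """Bin droplets by red peak and map bins to alpha via the calibration."""
    binner = AlphaBinner(calibration=cal, n_bins=n_bins,
                         min_bin_count=min_bin_count).fit()
    return binner.transform(red_peaks)


def find_size_modes(
    red_widths, red_peaks=None, n_modes: int = 2,
    coalescence_z: float = 4.0, seed: int = 0,
) -> PopulationAssignment:
    """Separate size modes on red width; flag coalescence outliers."""
    red_widths = np.asarray(red_widths, dtype=float).ravel()
    red_peaks = (np.zeros_like(red_widths) if red_peaks is None
                 else np.asarray(red_peaks, dtype=float).ravel())
    grouper = SizeModeGrouper(n_modes=n_modes, coalescence_z=coalescence_z,
                              random_state=seed).fit(red_widths)
    groups = _summarize(grouper.labels_, red_peaks, red_widths)
    return PopulationAssignment(
        labels=grouper.labels_,
        coalesced=grouper.coalesced_,
        groups=groups,
        discarded_fraction=float(np.mean(grouper.labels_ < 0)),
    )


def detect_droplets(trace: Trace, threshold: float | None = None,
                    hysteresis: float = 0.5) -> pd.DataFrame:
    """Segment a two-channel trace into droplet events on the red channel.

    A droplet starts when red rises above ``threshold`` and ends when it
    falls below ``hysteresis * threshold``.  Per event: red peak = max, red
    width = duration above half-max (converted back to width units via the
    trace's ``width_scale_s``), green peak = max in the event window.
    """
    red, green = trace.red, trace.green
    if red.size == 0 or red.max() <= 0:
        return _empty_events()
    if threshold is None:
        threshold = 0.25 * np.percentile(red, 99.9)
        if threshold <= 0:
            return _empty_events()
    lo = hysteresis * threshold
    above = red > threshold
    below = red < lo
    if np.mean(red >= red.max() * 0.999) > 0.5:
        warnings.warn("trace looks saturated/clipped; peak heights unreliable",
                      stacklevel=2)

    events = []
    inside = False
    start = 0
    for i in range(red.size):
        if not inside and above[i]:
            inside, start = True, i
        elif inside and below[i]:
            events.append((start, i))
            inside = False
    if inside:
        events.append((start, red.size))

    rows = []
    dt = 1.0 / trace.sampling_rate_hz
    for k, (s, e) in enumerate(events):
        seg = red[s:e]
        peak = seg.max()
        width_s = np.count_nonzero(seg >= 0.5 * peak) * dt
        rows.append({
            "droplet_id": k,
            "green_peak": float(green[s:e].max()),
            "red_peak": float(peak),
            "red_width": float(width_s / trace.width_scale_s),
            "time_min": np.nan,
        })
    return pd.DataFrame(rows) if rows else _empty_events()


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {c: pd.Series(dtype=t) for c, t in [
            ("droplet_id", "int64"), ("green_peak", "float64"),
            ("red_peak", "float64"), ("red_width", "float64"),
            ("time_min", "float64"),
        ]}
    )
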
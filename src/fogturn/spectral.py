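"""FOG-ratio and FOG-index from shin accelerometry.

The freeze index quantifies trembling-type freezing as the ratio of shin
acceleration power in the 3-8 Hz "freeze" band to power in the 0.5-3 Hz
"locomotion" band, computed on short sliding windows.  The trial-level
FOG-index divides the mean and maximum window ratio of each axis
(anterior-posterior and medio-lateral) by the number of completed 360°
turns, giving four metrics: AP_Mean, AP_Max, ML_Mean, ML_Max.

The locomotion-band denominator is floored at a small epsilon: during
akinetic freezing both bands lose power, but the locomotion band collapses
to the noise floor faster, so the floored ratio still rises — this is the
mechanism by which the index responds to akinetic as well as trembling
freezing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import IMUTrial

FREEZE_BAND = (3.0, 8.0)
LOCOMOTION_BAND = (0.5, 3.0)


@dataclass(frozen=True)
class SpectralConfig:
    """Windowing and band parameters for the FOG-ratio.

    ``window_s`` trades episode-scale time resolution against frequency
    resolution at the 0.5 Hz locomotion-band edge; 3 s (0.33 Hz bins) is the
    default, 4 s is the conservative alternative.  ``squared_ratio`` selects
    the squared-band-power variant of the freeze index; the plain ratio is
    the default.  ``pool_shins`` pools windows from both shins before the
    mean/max aggregation (captures unilateral trembling); the alternative
    averages per-shin aggregates.
    """

    freeze_band: tuple[float, float] = FREEZE_BAND
    locomotion_band: tuple[float, float] = LOCOMOTION_BAND
    window_s: float = 3.0
    overlap_fraction: float = 0.5
    taper: str = "hann"
    squared_ratio: bool = False
    pool_shins: bool = True
    loco_floor: float = 1e-8  # g^2; akinetic windows hit this floor

    def validate(self) -> "SpectralConfig":
        lo_f, hi_f = self.freeze_band
        lo_l, hi_l = self.locomotion_band
        if not (lo_l < hi_l <= lo_f < hi_f):
            raise ValueError(
                f"bands must be ordered and non-overlapping: "
                f"locomotion {self.locomotion_band}, freeze {self.freeze_band}"
            )
        if self.window_s * lo_l < 1.0:
            raise ValueError(
                f"window_s={self.window_s} cannot resolve the {lo_l} Hz "
                "locomotion-band edge (need window_s >= 1/edge)"
            )
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        return self


@dataclass(frozen=True)
class FogRatioSeries:
    """Per-window FOG-ratios for one trial, keyed by (shin, axis)."""

    window_centers_s: np.ndarray
    ratios: dict[tuple[str, str], np.ndarray]  # (shin, axis) -> per-window ratio

    def pooled(self, axis: str) -> np.ndarray:
        """All window ratios for one axis, both shins concatenated."""
        return np.concatenate(
            [v for (shin, ax), v in sorted(self.ratios.items()) if ax == axis]
        )


@dataclass(frozen=True)
class FogIndexResult:
    """The four FOG-index metrics with provenance."""

    ap_mean: float
    ap_max: float
    ml_mean: float
    ml_max: float
    n_turns: int
    fog_ratio_series: FogRatioSeries
    max_provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "AP_Mean": self.ap_mean,
            "AP_Max": self.ap_max,
            "ML_Mean": self.ml_mean,
            "ML_Max": self.ml_max,
        }


def band_power(psd_freqs: np.ndarray, psd_values: np.ndarray, band: tuple[float, float]) -> float:
    """Integrate a one-sided PSD over a frequency band (trapezoidal rule).

    Band edges falling between PSD bins are handled by linear interpolation
    of the PSD at the edges, so a flat PSD of height h over band width w
    integrates to exactly h*w.
    """
    freqs = np.asarray(psd_freqs, dtype=float)
    psd = np.asarray(psd_values, dtype=float)
    if freqs.ndim != 1 or freqs.size < 2 or np.any(np.diff(freqs) <= 0):
        raise ValueError("psd_freqs must be strictly increasing with >= 2 points")
    lo, hi = band
    if not (freqs[0] <= lo < hi <= freqs[-1]):
        raise ValueError(
            f"band {band} outside resolvable range [{freqs[0]}, {freqs[-1]}] Hz"
        )
    inside = (freqs > lo) & (freqs < hi)
    grid = np.concatenate(([lo], freqs[inside], [hi]))
    values = np.interp(grid, freqs, psd)
    return float(np.trapezoid(values, grid))


def _window_starts(n: int, nperseg: int, noverlap: int) -> np.ndarray:
    step = nperseg - noverlap
    # final partial window is dropped, not zero-padded
    return np.arange(0, n - nperseg + 1, step)


def window_psd(series: np.ndarray, sample_rate_hz: float, config: SpectralConfig):
    """Per-window one-sided PSD (taper per config, per-window mean removed).

    Returns (freqs, psd_matrix [n_windows x n_freqs], window_centers_s).
    """
    config.validate()
    x = np.asarray(series, dtype=float)
    nperseg = int(round(config.window_s * sample_rate_hz))
    noverlap = int(round(nperseg * config.overlap_fraction))
    if x.size < nperseg:
        raise ValueError(
            f"series of {x.size} samples shorter than one {config.window_s} s window"
        )
    starts = _window_starts(x.size, nperseg, noverlap)
    psds = []
    for s in starts:
        seg = x[s : s + nperseg]
        freqs, pxx = sps.periodogram(
            seg,
            fs=sample_rate_hz,
            window=config.taper,
            detrend="constant",
            scaling="density",
        )
        psds.append(pxx)
    centers = (starts + nperseg / 2.0) / sample_rate_hz
    return freqs, np.vstack(psds), centers


def fog_ratio_windows(
    series: np.ndarray, sample_rate_hz: float, config: SpectralConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed freeze-band / locomotion-band power ratio for one axis.

    Returns (window_centers_s, ratios).  The ratio is scale-invariant: a
    global amplitude rescaling of the input leaves it unchanged (up to the
    epsilon floor on the denominator).
    """
    config = (config or SpectralConfig()).validate()
    freqs, psds, centers = window_psd(series, sample_rate_hz, config)
    ratios = np.empty(psds.shape[0])
    for i, pxx in enumerate(psds):
        p_freeze = band_power(freqs, pxx, config.freeze_band)
        p_loco = max(band_power(freqs, pxx, config.locomotion_band), config.loco_floor)
        r = p_freeze / p_loco
        ratios[i] = r * r if config.squared_ratio else r
    return centers, ratios


def fog_index(
    trial: IMUTrial, n_turns: int, config: SpectralConfig | None = None
) -> FogIndexResult:
    """Compute the four FOG-index metrics for a trial.

    The mean and maximum window FOG-ratio of each axis (windows from both
    shins pooled by default) are divided by the number of completed turns.
    ``n_turns`` must be >= 1: with zero completed turns the index is
    undefined and an error is raised rather than returning NaN.
    """
    config = (config or SpectralConfig()).validate()
    trial.validate()
    if n_turns < 1:
        raise ValueError(
            "FOG-index undefined for n_turns=0: no completed turns to normalize by"
        )
    ratios: dict[tuple[str, str], np.ndarray] = {}
    centers = None
    for shin_name, chan_map in (("shin_L", trial.shin_left), ("shin_R", trial.shin_right)):
        for axis in ("AP", "ML"):
            c, r = fog_ratio_windows(chan_map[axis], trial.sample_rate_hz, config)
            ratios[(shin_name, axis)] = r
            centers = c
    series = FogRatioSeries(window_centers_s=centers, ratios=ratios)

    def aggregate(axis: str) -> tuple[float, float, dict]:
        if config.pool_shins:
            pooled = series.pooled(axis)
            mean_r, max_r = float(pooled.mean()), float(pooled.max())
        else:
            per_shin = [series.ratios[(s, axis)] for s in ("shin_L", "shin_R")]
            mean_r = float(np.mean([p.mean() for p in per_shin]))
            max_r = float(np.mean([p.max() for p in per_shin]))
        best_key, best_idx, best_val = None, None, -np.inf
        for (shin, ax), vals in sorted(series.ratios.items()):
            if ax != axis:
                continue
            i = int(np.argmax(vals))
            if vals[i] > best_val:
                best_key, best_idx, best_val = shin, i, float(vals[i])
        prov = {
            "shin": best_key,
            "window_index": best_idx,
            "window_center_s": float(series.window_centers_s[best_idx]),
        }
        return mean_r / n_turns, max_r / n_turns, prov

    ap_mean, ap_max, ap_prov = aggregate("AP")
    ml_mean, ml_max, ml_prov = aggregate("ML")
    return FogIndexResult(
        ap_mean=ap_mean,
        ap_max=ap_max,
        ml_mean=ml_mean,
        ml_max=ml_max,
        n_turns=int(n_turns),
        fog_ratio_series=series,
        max_provenance={"AP": ap_prov, "ML": ml_prov},
    )
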
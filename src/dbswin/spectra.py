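"""Subthalamic power-spectrum feature chain.

A contact channel is turned into seven band-power features through a fixed
sequence of stages:

``raw`` -- Welch periodogram over 2 s windows with 50 % overlap, evaluated at
integer frequencies 1-300 Hz.

``denoised`` -- power around 50 Hz line noise and its harmonics replaced by
linear interpolation between the nearest clean bins.

``periodic`` -- the aperiodic (1/f) background is fitted and subtracted in
log10 units: a knee-free power-law fit up to 90 Hz (robust to oscillatory
peaks) and a linear detrend of log10 power vs frequency above 90 Hz.

Band powers are arithmetic means of the periodic residual over the integer
frequencies of each band, limits inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "EpochedRecording",
    "Spectrum",
    "BandScheme",
    "DEFAULT_BANDS",
    "welch_psd",
    "welch_full",
    "interpolate_line_noise",
    "remove_aperiodic",
    "band_power",
]

#: analysed frequency range, integer Hz
FMIN, FMAX = 1, 300
#: epoch length in seconds; 2 s windows give 0.5 Hz resolution
EPOCH_SECONDS = 2.0

_STAGES = ("raw", "denoised", "periodic")


@dataclass
class EpochedRecording:
    """Per-patient multichannel resting-state recording.

    Channels are STN contact channels (role ``"stn"``, with an electrode
    side and a contact id) and cortical parcel channels (role ``"parcel"``).
    The signal is stored continuously; the 2 s epoching is applied by the
    spectral and coherence estimators.
    """

    patient_id: str
    fs: float
    data: np.ndarray  # (n_channels, n_samples)
    labels: list
    roles: list  # "stn" | "parcel" per channel
    sides: list  # "left" | "right" for stn channels, None for parcels
    contact_ids: list  # contact id for stn channels, None for parcels

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.roles) == len(self.sides)
                == len(self.contact_ids) == n):
            raise ValueError("channel metadata length mismatch")
        if self.data.shape[1] < int(round(EPOCH_SECONDS * self.fs)):
            raise ValueError("recording shorter than one 2 s epoch")

    def channel(self, label) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def stn_index(self, side: str) -> list:
        return [i for i, (r, s) in enumerate(zip(self.roles, self.sides))
                if r == "stn" and s == side]

    @property
    def parcel_index(self) -> list:
        return [i for i, r in enumerate(self.roles) if r == "parcel"]

    @property
    def parcel_labels(self) -> list:
        return [self.labels[i] for i in self.parcel_index]


@dataclass
class Spectrum:
    """Power vs integer frequency with processing-stage provenance.

    ``power`` is linear for stages ``raw``/``denoised`` and a signed log10
    residual for stage ``periodic``.  ``interpolated`` marks bins whose value
    was replaced during line-noise removal; those bins are excluded from the
    >90 Hz detrend fit.
    """

    freqs: np.ndarray
    power: np.ndarray
    stage: str = "raw"
    interpolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs)
        self.power = np.asarray(self.power, dtype=float)
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.interpolated is None:
            self.interpolated = np.zeros(self.freqs.shape, dtype=bool)


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands, limits in Hz and inclusive on both sides.

    The default seven-band scheme spans theta through high-frequency
    oscillations (HFO).  Note that 60 Hz belongs to both low and high gamma;
    the overlap is intentional and preserved.
    """

    bands: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not (FMIN <= lo <= hi <= FMAX):
                raise ValueError(f"band {name!r} outside {FMIN}-{FMAX} Hz")

    @property
    def names(self) -> list[str]:
        return list(self.bands)


DEFAULT_BANDS: dict[str, tuple[int, int]] = {
    "theta": (3, 7),
    "alpha": (8, 12),
    "low_beta": (13, 20),
    "high_beta": (21, 35),
    "low_gamma": (36, 60),
    "high_gamma": (60, 90),
    "hfo": (200, 300),
}


def _check_fs(fs: float) -> None:
    # HFO band extends to 300 Hz; need Nyquist above it
    if fs <= 2 * FMAX:
        raise ValueError(f"sampling rate {fs} Hz too low; need > {2 * FMAX} Hz")


def welch_full(x: np.ndarray, fs: float, *, overlap: float = 0.5):
    """Welch PSD of a channel on the full 0.5 Hz grid.

    Hann taper, one-sided density.  Returns ``(freqs, psd)``; integrating
    the density over frequency recovers the signal variance (Parseval).
    """
    _check_fs(fs)
    x = np.asarray(x, dtype=float)
    nperseg = int(round(EPOCH_SECONDS * fs))
    if x.size < nperseg:
        raise ValueError(
            f"signal too short: need at least one {EPOCH_SECONDS:g} s epoch"
        )
    noverlap = int(round(nperseg * overlap))
    return sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant",
    )


def welch_psd(x: np.ndarray, fs: float) -> Spectrum:
    """Welch power spectrum sampled at integer frequencies 1-300 Hz."""
    f, p = welch_full(x, fs)
    # 2 s epochs give a 0.5 Hz grid; integer frequencies are every 2nd bin
    idx = np.nonzero(np.isclose(f % 1.0, 0.0) & (f >= FMIN) & (f <= FMAX))[0]
    freqs = np.round(f[idx]).astype(int)
    return Spectrum(freqs=freqs, power=p[idx], stage="raw")


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for lo, hi in sorted(iv):
        if out and lo <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def interpolate_line_noise(
    s: Spectrum, base: float = 50.0, halfwidth: float = 7.0
) -> Spectrum:
    """Replace power near line-noise harmonics by linear interpolation.

    Bins strictly within ``halfwidth`` Hz of each harmonic of ``base`` are
    replaced by the straight line joining the nearest bins outside the notch
    (43 and 57 Hz for the 50 Hz fundamental).  A harmonic with no clean bin
    to its right (300 Hz) is filled flat from the left anchor.  Overlapping
    notches are merged.  All bins outside the notches are left untouched.
    """
    if s.stage != "raw":
        raise ValueError(f"expected stage 'raw', got {s.stage!r}")
    freqs = s.freqs
    power = s.power.copy()
    notched = np.zeros(freqs.shape, dtype=bool)

    harmonics = np.arange(base, freqs[-1] + halfwidth, base)
    intervals = []
    for h in harmonics:
        inside = np.abs(freqs - h) < halfwidth
        if inside.any():
            idx = np.nonzero(inside)[0]
            intervals.append((int(idx[0]), int(idx[-1])))
    for lo, hi in _merge_intervals(intervals):
        left = lo - 1
        right = hi + 1
        if left < 0 and right >= freqs.size:
            raise ValueError("notch covers the entire spectrum")
        if right >= freqs.size:
            # no right anchor: extrapolate flat from the left anchor
            power[lo : hi + 1] = power[left]
        elif left < 0:
            power[lo : hi + 1] = power[right]
        else:
            power[lo : hi + 1] = np.interp(
                freqs[lo : hi + 1],
                [freqs[left], freqs[right]],
                [power[left], power[right]],
            )
        notched[lo : hi + 1] = True

    return replace(s, power=power, stage="denoised", interpolated=notched)


def _robust_powerlaw_fit(
    log_f: np.ndarray, log_p: np.ndarray, n_iter: int = 5, pct: float = 97.5
):
    """Knee-free aperiodic fit, iteratively down-weighting oscillatory peaks.

    Fits log10 power = b - chi * log10 f by least squares, then refits after
    masking bins whose positive residual exceeds the ``pct`` percentile of
    positive residuals -- peaks sit above the background, so only upward
    outliers are excluded.
    """
    mask = np.ones(log_f.size, dtype=bool)
    coef = np.polyfit(log_f, log_p, 1)
    for _ in range(n_iter):
        resid = log_p - np.polyval(coef, log_f)
        pos = resid[resid > 0]
        if pos.size == 0:
            break
        thresh = np.percentile(pos, pct) * 0.5
        new_mask = resid <= max(thresh, 1e-12)
        if new_mask.sum() < 3:
            break
        mask = new_mask
        coef = np.polyfit(log_f[mask], log_p[mask], 1)
    return coef


def remove_aperiodic(s: Spectrum, split: float = 90.0) -> Spectrum:
    """Subtract the aperiodic background, retaining the periodic residual.

    Below ``split`` Hz the background is modelled as a power law in log-log
    space (fixed mode, no knee) fitted robustly against oscillatory peaks.
    Above ``split`` Hz a straight line in log10 power vs linear frequency is
    fitted -- excluding line-noise-interpolated bins -- and subtracted.  The
    returned power is the signed log10 residual.
    """
    if s.stage != "denoised":
        raise ValueError(f"expected stage 'denoised', got {s.stage!r}")
    if np.any(s.power <= 0):
        raise ValueError("non-positive power; cannot take log10")

    freqs = s.freqs.astype(float)
    log_p = np.log10(s.power)
    resid = np.empty_like(log_p)

    low = freqs <= split
    coef = _robust_powerlaw_fit(np.log10(freqs[low]), log_p[low])
    resid[low] = log_p[low] - np.polyval(coef, np.log10(freqs[low]))

    high = ~low
    if high.any():
        fit_mask = high & ~s.interpolated
        if fit_mask.sum() < 2:
            fit_mask = high
        lin = np.polyfit(freqs[fit_mask], log_p[fit_mask], 1)
        resid[high] = log_p[high] - np.polyval(lin, freqs[high])

    return replace(s, power=resid, stage="periodic")


def band_power(s: Spectrum, scheme: BandScheme | None = None) -> np.ndarray:
    """Mean periodic residual per band (limits inclusive), in scheme order."""
    if s.stage != "periodic":
        raise ValueError(f"expected stage 'periodic', got {s.stage!r}")
    scheme = scheme or BandScheme()
    out = np.empty(len(scheme.bands))
    for i, (lo, hi) in enumerate(scheme.bands.values()):
        sel = (s.freqs >= lo) & (s.freqs <= hi)
        out[i] = s.power[sel].mean()
    return out


def periodic_spectrum(x: np.ndarray, fs: float) -> Spectrum:
    """Full chain raw -> denoised -> periodic for one channel."""
    return remove_aperiodic(interpolate_line_noise(welch_psd(x, fs)))


def stn_band_features(x: np.ndarray, fs: float,
                      scheme: BandScheme | None = None) -> np.ndarray:
    """Seven STN band-power features for one contact channel."""
    return band_power(periodic_spectrum(x, fs), scheme)
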
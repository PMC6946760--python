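"""The 8 frequency-domain features, computed on the unpadded FFT of each window.

Spectral statistics with a physical frequency axis (MNF, MDF, MPK, STDPK,
FR, PKF) use the one-sided spectrum; the spectral waveform length and the
10 Hz-binned frequency-energy vector use the full two-sided FFT array.
At 2000 Hz and 400-sample windows the bin spacing is 5 Hz and the FE
vector has 200 bins per channel, so all 8 blocks on 4 channels give
7*4 + 200*4 = 828 feature columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .signal_model import FeatureColumn, WindowSet

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum", "BandConfig", "spectrum", "wl_fd", "mnf", "mdf",
    "spectral_peaks", "fr", "pkf", "fe",
    "FD_BLOCKS", "fd_block_arity", "compute_fd_block",
]


@dataclass(frozen=True)
class Spectrum:
    """Magnitude/power spectrum of one window.

    ``sided='one'`` covers 0..fs/2 with floor(N/2)+1 bins; ``'two'`` keeps
    the full N-point FFT over 0..fs*(N-1)/N.
    """

    mag: np.ndarray
    power: np.ndarray
    freqs: np.ndarray
    delta_f: float
    sided: str


@dataclass(frozen=True)
class BandConfig:
    """Low/high band edges (Hz) for the frequency ratio.

    Membership: low band [low_lo, low_hi), high band [high_lo, high_hi].
    """

    low_lo: float = 10.0
    low_hi: float = 250.0
    high_lo: float = 250.0
    high_hi: float = 500.0


def _nan(msg: str) -> float:
    logger.warning(msg)
    return float("nan")


def spectrum(x: np.ndarray, fs: float, sided: str = "one") -> Spectrum:
    """Unpadded FFT spectrum of a window."""
    x = np.asarray(x, float)
    N = len(x)
    if N < 2:
        raise ValueError("need at least two samples")
    if sided == "one":
        X = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(N, d=1.0 / fs)
    elif sided == "two":
        X = np.fft.fft(x)
        freqs = np.arange(N) * fs / N
    else:
        raise ValueError("sided must be 'one' or 'two'")
    mag = np.abs(X)
    return Spectrum(mag, mag**2, freqs, fs / N, sided)


def wl_fd(s: Spectrum) -> float:
    """Waveform length of the two-sided FFT magnitude vector."""
    if s.sided != "two":
        raise ValueError("spectral waveform length is defined on the two-sided spectrum")
    return float(np.sum(np.abs(np.diff(s.mag))))


def mnf(s: Spectrum) -> float:
    """Mean (power-weighted average) frequency in Hz."""
    if s.sided != "one":
        raise ValueError("mean frequency needs the one-sided spectrum")
    total = float(np.sum(s.power))
    if total == 0.0:
        return _nan("mean frequency undefined for zero power")
    return float(np.sum(s.freqs * s.power) / total)


def mdf(s: Spectrum) -> float:
    """Median frequency: smallest bin where cumulative power reaches half the total."""
    if s.sided != "one":
        raise ValueError("median frequency needs the one-sided spectrum")
    total = float(np.sum(s.power))
    if total == 0.0:
        return _nan("median frequency undefined for zero power")
    cum = np.cumsum(s.power)
    # tiny relative slack so a bin holding exactly half the power wins the tie
    idx = int(np.searchsorted(cum, 0.5 * total * (1.0 - 1e-12)))
    return float(s.freqs[idx])


def spectral_peaks(s: Spectrum) -> tuple[float, float]:
    """(MPK, STDPK): mean and sample STD of magnitude bins above the spectrum RMS."""
    if s.sided != "one":
        raise ValueError("spectral peaks need the one-sided spectrum")
    rms = math.sqrt(float(np.mean(s.mag**2)))
    peaks = s.mag[s.mag > rms]
    if len(peaks) == 0:
        v = _nan("no spectral bins exceed the spectrum RMS")
        return v, v
    mpk = float(np.mean(peaks))
    stdpk = float(np.std(peaks, ddof=1)) if len(peaks) > 1 else 0.0
    return mpk, stdpk


def fr(s: Spectrum, bands: BandConfig | None = None) -> float:
    """Ratio of low-band to high-band spectral power."""
    if s.sided != "one":
        raise ValueError("frequency ratio needs the one-sided spectrum")
    b = bands or BandConfig()
    low = (s.freqs >= b.low_lo) & (s.freqs < b.low_hi)
    high = (s.freqs >= b.high_lo) & (s.freqs <= b.high_hi)
    p_high = float(np.sum(s.power[high]))
    # a band holding only FFT round-off noise counts as empty
    if p_high <= 1e-12 * float(np.sum(s.power)):
        return _nan("frequency ratio undefined: zero high-band power")
    return float(np.sum(s.power[low]) / p_high)


def pkf(s: Spectrum) -> float:
    """Frequency (Hz) of the maximum power bin; ties go to the lowest frequency."""
    if s.sided != "one":
        raise ValueError("peak frequency needs the one-sided spectrum")
    pmax = float(np.max(s.power))
    if pmax == 0.0:
        return _nan("peak frequency undefined for zero power")
    # near-ties (within FFT round-off) go to the lowest frequency
    idx = int(np.flatnonzero(s.power >= pmax * (1.0 - 1e-9))[0])
    return float(s.freqs[idx])


def n_fe_bins(N: int, fs: float, bin_hz: float = 10.0) -> int:
    """Number of 10 Hz bins covering the full two-sided frequency axis."""
    return int((fs * (N - 1) / N) // bin_hz) + 1


def fe(s: Spectrum, bin_hz: float = 10.0) -> np.ndarray:
    """Squared FFT amplitudes of one channel summed into contiguous 10 Hz bins.

    Computed over the full two-sided 0..fs axis (200 bins for 400 samples
    at 2000 Hz); the bin sums conserve the total spectral energy exactly.
    """
    if s.sided != "two":
        raise ValueError("frequency energy needs the two-sided spectrum")
    idx = (s.freqs // bin_hz).astype(int)
    out = np.zeros(idx[-1] + 1)
    np.add.at(out, idx, s.power)
    return out


# ---------------------------------------------------------------------------
# Block computation over a WindowSet
# ---------------------------------------------------------------------------

_SCALARS = {
    "WLFD": lambda s1, s2, bands: wl_fd(s2),
    "MNF": lambda s1, s2, bands: mnf(s1),
    "MDF": lambda s1, s2, bands: mdf(s1),
    "MPK": lambda s1, s2, bands: spectral_peaks(s1)[0],
    "STDPK": lambda s1, s2, bands: spectral_peaks(s1)[1],
    "FR": lambda s1, s2, bands: fr(s1, bands),
    "PKF": lambda s1, s2, bands: pkf(s1),
}

#: The 8 FD feature blocks in canonical order.
FD_BLOCKS = ("WLFD", "MNF", "MDF", "MPK", "STDPK", "FR", "PKF", "FE")


def fd_block_arity(name: str, n_channels: int, N: int, fs: float) -> int:
    if name == "FE":
        return n_fe_bins(N, fs) * n_channels
    if name in _SCALARS:
        return n_channels
    raise KeyError(name)


def compute_fd_block(name: str, ws: WindowSet, bands: BandConfig | None = None):
    """Compute one FD feature block for every window; returns (values, columns)."""
    bands = bands or BandConfig()
    w, C = ws.n_windows, ws.n_channels
    ch = [f"ch{c + 1}" for c in range(C)]
    if name in _SCALARS:
        fn = _SCALARS[name]
        values = np.empty((w, C))
        for i in range(w):
            for c in range(C):
                x = ws.windows[i, c]
                s1 = spectrum(x, ws.fs, "one")
                s2 = spectrum(x, ws.fs, "two") if name == "WLFD" else None
                values[i, c] = fn(s1, s2, bands)
        cols = [FeatureColumn(name, "value", c) for c in ch]
    elif name == "FE":
        nb = n_fe_bins(ws.N, ws.fs)
        values = np.zeros((w, nb * C))
        for i in range(w):
            for c in range(C):
                v = fe(spectrum(ws.windows[i, c], ws.fs, "two"))
                values[i, c * nb : c * nb + len(v)] = v
        cols = [FeatureColumn(name, f"bin{b + 1}", c) for c in ch for b in range(nb)]
    else:
        raise KeyError(f"unknown FD block {name!r}")
    return values, tuple(cols)
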
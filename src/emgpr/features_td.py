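"""The 25 time-domain features, computed per 200 ms window.

Most features are scalars per channel; the correlation coefficient is
emitted per unordered channel pair (6 values for 4 channels), the
multi-channel energy ratio yields 3 values for 4 channels, and the
amplitude histogram yields ``hist_bins`` counts per channel.  With the
defaults on a 4-channel window this gives 22*4 + 6 + 3 + 9*4 = 133
feature columns.

Degenerate inputs (e.g. a constant window where a variance-normalised
feature is undefined) return NaN and log a warning, except where zero is
the genuine limit (waveform length and its relatives).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .signal_model import FeatureColumn, WindowSet

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdConfig",
    "mav", "std", "var", "wl", "zc", "peak_trio", "ssc", "cor", "damv",
    "fdim_curve_length", "mfl", "hfd", "skew", "kurt", "iav",
    "hjorth_mobility", "hjorth_complexity", "energy_ratio", "dasdv",
    "wam", "mavs", "perc75", "hist",
    "TD_BLOCKS", "td_block_arity", "compute_td_block",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds and small integer parameters for TD features."""

    ssc_threshold: float = 0.0
    wam_threshold: float = 0.0
    hist_bins: int = 9
    fdim_k: int = 1
    fdim_kmax: int = 10


def _nan(msg: str) -> float:
    logger.warning(msg)
    return float("nan")


def mav(x: np.ndarray) -> float:
    """Mean absolute value."""
    return float(np.mean(np.abs(x)))


def std(x: np.ndarray) -> float:
    """Sample standard deviation (mean-subtracted, N-1 denominator)."""
    return float(np.std(x, ddof=1))


def var(x: np.ndarray) -> float:
    """Signal power: sum of squares over N-1, without mean subtraction.

    This is the raw second moment (scaled by N/(N-1)), appropriate for
    band-passed EMG which is essentially zero-mean; it doubles as the
    Hjorth activity parameter in the feature table.
    """
    x = np.asarray(x, float)
    return float(np.sum(x * x) / (len(x) - 1))


def wl(x: np.ndarray) -> float:
    """Waveform length: total variation of the window."""
    return float(np.sum(np.abs(np.diff(x))))


def zc(x: np.ndarray) -> int:
    """Zero crossings: adjacent pairs with strictly opposite signs.

    Exact zeros never count (sgn(0) = 0 convention).
    """
    x = np.asarray(x, float)
    return int(np.sum(x[1:] * x[:-1] < 0))


def peak_trio(x: np.ndarray) -> tuple[int, float, float]:
    """(NP, MPV, MFV): peaks are raw samples strictly above the window RMS.

    MPV is the mean peak value; MFV the mean of successive peak
    differences (the "firing velocity").  Fewer than one peak gives
    MPV = MFV = 0; a single peak gives MFV = 0.
    """
    x = np.asarray(x, float)
    rms = math.sqrt(float(np.mean(x * x)))
    peaks = x[x > rms]
    np_count = int(len(peaks))
    mpv = float(np.mean(peaks)) if np_count else 0.0
    mfv = float(np.mean(np.diff(peaks))) if np_count > 1 else 0.0
    return np_count, mpv, mfv


def ssc(x: np.ndarray, threshold: float = 0.0) -> int:
    """Slope sign changes: interior samples whose slope product exceeds the threshold."""
    x = np.asarray(x, float)
    prod = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    return int(np.sum(prod > threshold))


def cor(xa: np.ndarray, xb: np.ndarray) -> float:
    """Absolute Pearson correlation between two channels (in [0, 1])."""
    xa = np.asarray(xa, float)
    xb = np.asarray(xb, float)
    da, db = xa - xa.mean(), xb - xb.mean()
    denom = math.sqrt(float(np.sum(da * da) * np.sum(db * db)))
    if denom == 0.0:
        logger.warning("correlation undefined for constant channel; returning 0")
        return 0.0
    return float(abs(np.sum(da * db)) / denom)


def damv(x: np.ndarray) -> float:
    """Difference absolute mean value: waveform length over N (as defined, 1/N)."""
    return float(np.sum(np.abs(np.diff(x))) / len(x))


def fdim_curve_length(x: np.ndarray, k: int) -> float:
    """Curve length of the signal resampled at stride ``k`` (Higuchi-style).

    Uses 0-based indexing with a single offset: the sum runs over
    i = 1..floor((N-1)/k) of \\|X(ik) - X((i-1)k)\\|, scaled by (N-1)/(N k).
    """
    x = np.asarray(x, float)
    N = len(x)
    if not 1 <= k < N:
        raise ValueError(f"stride k={k} must satisfy 1 <= k < N={N}")
    idx = np.arange(0, N, k)
    total = float(np.sum(np.abs(np.diff(x[idx]))))
    return total * (N - 1) / N / k


def hfd(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension from curve lengths at strides 1 and kmax."""
    x = np.asarray(x, float)
    if len(x) <= kmax:
        raise ValueError("window shorter than kmax")
    f1 = fdim_curve_length(x, 1)
    fk = fdim_curve_length(x, kmax)
    if f1 <= 0 or fk <= 0:
        return _nan("HFD undefined for zero curve length")
    return (math.log10(f1) - math.log10(fk)) / math.log10(kmax)


def mfl(x: np.ndarray) -> float:
    """Maximum fractal length: log10 of the RMS-free total squared variation."""
    ssq = float(np.sum(np.diff(np.asarray(x, float)) ** 2))
    if ssq == 0.0:
        return _nan("MFL undefined for a constant window")
    return math.log10(math.sqrt(ssq))


def _central_moments(x: np.ndarray) -> tuple[float, float, float]:
    x = np.asarray(x, float)
    d = x - x.mean()
    return float(np.mean(d**2)), float(np.mean(d**3)), float(np.mean(d**4))


def skew(x: np.ndarray) -> float:
    """Skewness M3 / M2^1.5 (biased central moments)."""
    m2, m3, _ = _central_moments(x)
    if m2 == 0.0:
        return _nan("skewness undefined for a constant window")
    return m3 / (m2 * math.sqrt(m2))


def kurt(x: np.ndarray) -> float:
    """Kurtosis M4 / M2^2 (biased central moments, not excess)."""
    m2, _, m4 = _central_moments(x)
    if m2 == 0.0:
        return _nan("kurtosis undefined for a constant window")
    return m4 / (m2 * m2)


def iav(x: np.ndarray) -> float:
    """Integrated absolute value (= N * MAV)."""
    return float(np.sum(np.abs(x)))


def _var_centered(x: np.ndarray) -> float:
    return float(np.var(x, ddof=1))


def hjorth_mobility(x: np.ndarray) -> float:
    """Hjorth mobility: sqrt(Var(dx)/Var(x)) with mean-subtracted variances."""
    x = np.asarray(x, float)
    v = _var_centered(x)
    if v == 0.0:
        return _nan("Hjorth mobility undefined for a constant window")
    return math.sqrt(_var_centered(np.diff(x)) / v)


def hjorth_complexity(x: np.ndarray) -> float:
    """Hjorth complexity: mobility of the derivative over mobility of the signal.

    Equals 1 for a densely sampled pure sinusoid.
    """
    x = np.asarray(x, float)
    m = hjorth_mobility(x)
    if not np.isfinite(m) or m == 0.0:
        return _nan("Hjorth complexity undefined")
    md = hjorth_mobility(np.diff(x))
    if not np.isfinite(md):
        return _nan("Hjorth complexity undefined")
    return md / m


def energy_ratio(window: np.ndarray) -> np.ndarray:
    """Multi-channel energy ratios ER_jk = E_j * E_1 / E_k^2.

    ``window`` is channels x N.  With 1-based channel numbering, j runs
    over 2..M-1 and k over j+1..M, giving 3 values for 4 channels.
    """
    w = np.asarray(window, float)
    M = w.shape[0]
    if M < 3:
        raise ValueError("energy ratio needs at least 3 channels")
    E = np.sum(w * w, axis=1)
    out = []
    for j in range(1, M - 1):          # 0-based j -> channels 2..M-1
        for k in range(j + 1, M):
            if E[k] == 0.0 or E[0] == 0.0:
                out.append(_nan(f"energy ratio undefined: zero energy in channel {k + 1} or 1"))
            else:
                out.append(E[j] * E[0] / E[k] ** 2)
    return np.array(out)


def dasdv(x: np.ndarray) -> float:
    """Standard deviation of adjacent-sample differences (N-1 denominator)."""
    x = np.asarray(x, float)
    d = np.diff(x)
    return math.sqrt(float(np.sum(d * d)) / (len(x) - 1))


def wam(x: np.ndarray, threshold: float = 0.0) -> int:
    """Willison amplitude: adjacent differences whose magnitude exceeds the threshold."""
    return int(np.sum(np.abs(np.diff(np.asarray(x, float))) > threshold))


def mavs(mav_sequence: np.ndarray) -> np.ndarray:
    """MAV slope: forward difference of per-window MAVs within one contraction.

    The difference MAV_{i+1} - MAV_i is assigned to window i; the final
    window of the sequence gets 0 so the per-window arity stays 1.
    """
    m = np.asarray(mav_sequence, float)
    out = np.zeros_like(m)
    if len(m) > 1:
        out[:-1] = np.diff(m)
    return out


def perc75(x: np.ndarray) -> float:
    """75th percentile by nearest rank on the raw sample values."""
    s = np.sort(np.asarray(x, float))
    idx = min(int(0.75 * len(s)), len(s) - 1)
    return float(s[idx])


def hist(x: np.ndarray, bins: int = 9) -> np.ndarray:
    """Amplitude histogram over ``bins`` equal-width bins spanning [min, max].

    A constant window puts all N samples in the first bin.
    """
    x = np.asarray(x, float)
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        counts = np.zeros(bins, dtype=int)
        counts[0] = len(x)
        return counts
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    return counts


# ---------------------------------------------------------------------------
# Block computation over a WindowSet
# ---------------------------------------------------------------------------

_SCALAR_FUNCS = {
    "MAV": lambda x, cfg: mav(x),
    "STD": lambda x, cfg: std(x),
    "VAR": lambda x, cfg: var(x),
    "WL": lambda x, cfg: wl(x),
    "ZC": lambda x, cfg: float(zc(x)),
    "NP": lambda x, cfg: float(peak_trio(x)[0]),
    "MPV": lambda x, cfg: peak_trio(x)[1],
    "MFV": lambda x, cfg: peak_trio(x)[2],
    "SSC": lambda x, cfg: float(ssc(x, cfg.ssc_threshold)),
    "DAMV": lambda x, cfg: damv(x),
    "FDIM": lambda x, cfg: fdim_curve_length(x, cfg.fdim_k),
    "MFL": lambda x, cfg: mfl(x),
    "HFD": lambda x, cfg: hfd(x, cfg.fdim_kmax),
    "SKEW": lambda x, cfg: skew(x),
    "IAV": lambda x, cfg: iav(x),
    "HMOB": lambda x, cfg: hjorth_mobility(x),
    "HCOM": lambda x, cfg: hjorth_complexity(x),
    "DASDV": lambda x, cfg: dasdv(x),
    "WAM": lambda x, cfg: float(wam(x, cfg.wam_threshold)),
    "KURT": lambda x, cfg: kurt(x),
    "PERC": lambda x, cfg: perc75(x),
}

#: The 25 TD feature blocks in their canonical order.
TD_BLOCKS = (
    "MAV", "STD", "VAR", "WL", "ZC", "NP", "MPV", "MFV", "SSC", "COR",
    "DAMV", "FDIM", "MFL", "HFD", "SKEW", "IAV", "HMOB", "HCOM", "ER",
    "DASDV", "WAM", "MAVS", "KURT", "PERC", "HIST",
)


def td_block_arity(name: str, n_channels: int, cfg: ThresholdConfig) -> int:
    if name == "COR":
        return n_channels * (n_channels - 1) // 2
    if name == "ER":
        return (n_channels - 1) * (n_channels - 2) // 2
    if name == "HIST":
        return cfg.hist_bins * n_channels
    if name in _SCALAR_FUNCS or name == "MAVS":
        return n_channels
    raise KeyError(name)


def compute_td_block(name: str, ws: WindowSet, cfg: ThresholdConfig | None = None):
    """Compute one TD feature block for every window.

    Returns ``(values, columns)`` where values is windows x arity.
    """
    cfg = cfg or ThresholdConfig()
    w, C = ws.n_windows, ws.n_channels
    ch = [f"ch{c + 1}" for c in range(C)]

    if name in _SCALAR_FUNCS:
        fn = _SCALAR_FUNCS[name]
        values = np.array([[fn(ws.windows[i, c], cfg) for c in range(C)] for i in range(w)], float).reshape(w, C)
        cols = [FeatureColumn(name, "value", c) for c in ch]
    elif name == "COR":
        pairs = [(a, b) for a in range(C) for b in range(a + 1, C)]
        values = np.array(
            [[cor(ws.windows[i, a], ws.windows[i, b]) for a, b in pairs] for i in range(w)], float
        ).reshape(w, len(pairs))
        cols = [FeatureColumn(name, "value", f"ch{a + 1}-ch{b + 1}") for a, b in pairs]
    elif name == "ER":
        values = np.array([energy_ratio(ws.windows[i]) for i in range(w)], float).reshape(w, -1)
        cols = [
            FeatureColumn(name, "value", f"ch{j + 1}-ch{k + 1}")
            for j in range(1, C - 1)
            for k in range(j + 1, C)
        ]
    elif name == "MAVS":
        mavs_vals = np.zeros((w, C))
        mav_all = np.array([[mav(ws.windows[i, c]) for c in range(C)] for i in range(w)], float).reshape(w, C)
        for ent in np.unique(ws.entry_index) if w else []:
            sel = np.flatnonzero(ws.entry_index == ent)
            for c in range(C):
                mavs_vals[sel, c] = mavs(mav_all[sel, c])
        values = mavs_vals
        cols = [FeatureColumn(name, "value", c) for c in ch]
    elif name == "HIST":
        values = np.array(
            [np.concatenate([hist(ws.windows[i, c], cfg.hist_bins) for c in range(C)]) for i in range(w)], float
        ).reshape(w, cfg.hist_bins * C)
        cols = [FeatureColumn(name, f"bin{b + 1}", c) for c in ch for b in range(cfg.hist_bins)]
    else:
        raise KeyError(f"unknown TD block {name!r}")
    return values, tuple(cols)
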
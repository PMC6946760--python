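"""The 11 time-frequency features from level-4 wavelet decompositions.

Eight statistics are computed on the concatenated level-4 DWT
approximation+detail coefficients (4th-order Coiflet), and three features
— log RMS, relative energy and normalised log energy — are computed per
subspace of the full level-4 wavelet-packet tree (5th-order Symmlet,
16 frequency-ordered subspaces).  Periodization boundary handling keeps
exactly N/2^4 coefficients per band (25 for a 400-sample window), which
makes the Parseval identities and the normalised-log-energy denominator
exact.  On 4 channels: 8*4 + 3*16*4 = 224 feature columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pywt

from .signal_model import FeatureColumn, WindowSet
from . import features_td as td

logger = logging.getLogger(__name__)

__all__ = [
    "WaveletConfig", "WaveletCoeffs", "WaveletPacketCoeffs",
    "dwt_level4", "dwt_stats", "wpt_level4", "logrms", "relative_energy", "nle",
    "TFD_BLOCKS", "DWT_STATS", "tfd_block_arity", "compute_tfd_block",
]

DWT_STATS = ("STD", "VAR", "WL", "ENERGY", "MAXAV", "ZC", "MEAN", "MAV")


@dataclass(frozen=True)
class WaveletConfig:
    dwt_wavelet: str = "coif4"
    wpt_wavelet: str = "sym5"
    level: int = 4
    mode: str = "periodization"


@dataclass(frozen=True)
class WaveletCoeffs:
    """Level-4 DWT approximation (A4) and detail (D4) coefficients."""

    A4: np.ndarray
    D4: np.ndarray
    details: tuple[np.ndarray, ...]  # D1..D3 (kept for energy checks)

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.A4, self.D4])


@dataclass(frozen=True)
class WaveletPacketCoeffs:
    """Full level-4 wavelet-packet tree: 16 frequency-ordered subspaces."""

    subspaces: tuple[np.ndarray, ...]

    @property
    def energies(self) -> np.ndarray:
        return np.array([float(np.sum(s * s)) for s in self.subspaces])

    @property
    def total_energy(self) -> float:
        return float(self.energies.sum())


def dwt_level4(x: np.ndarray, cfg: WaveletConfig | None = None) -> WaveletCoeffs:
    """Multi-level DWT of one window; keeps the last-level A and D bands."""
    cfg = cfg or WaveletConfig()
    x = np.asarray(x, float)
    if len(x) < 2**cfg.level:
        raise ValueError(f"window of {len(x)} samples too short for level {cfg.level}")
    coeffs = pywt.wavedec(x, cfg.dwt_wavelet, mode=cfg.mode, level=cfg.level)
    return WaveletCoeffs(coeffs[0], coeffs[1], tuple(coeffs[2:]))


def dwt_stats(c: WaveletCoeffs) -> dict[str, float]:
    """Eight statistics of the combined level-4 coefficient vector.

    STD/VAR/WL/ZC/MAV reuse the time-domain operators; ENERGY is the sum
    of squares and MAXAV the largest absolute coefficient.
    """
    v = c.combined
    return {
        "STD": td.std(v),
        "VAR": td.var(v),
        "WL": td.wl(v),
        "ENERGY": float(np.sum(v * v)),
        "MAXAV": float(np.max(np.abs(v))),
        "ZC": float(td.zc(v)),
        "MEAN": float(np.mean(v)),
        "MAV": td.mav(v),
    }


def wpt_level4(x: np.ndarray, cfg: WaveletConfig | None = None) -> WaveletPacketCoeffs:
    """Full level-4 wavelet-packet decomposition, subspaces in frequency order."""
    cfg = cfg or WaveletConfig()
    x = np.asarray(x, float)
    if len(x) < 2**cfg.level:
        raise ValueError(f"window of {len(x)} samples too short for level {cfg.level}")
    wp = pywt.WaveletPacket(x, cfg.wpt_wavelet, mode=cfg.mode, maxlevel=cfg.level)
    nodes = wp.get_level(cfg.level, order="freq")
    return WaveletPacketCoeffs(tuple(np.asarray(n.data, float) for n in nodes))


def _nan(msg: str) -> float:
    logger.warning(msg)
    return float("nan")


def logrms(p: WaveletPacketCoeffs) -> np.ndarray:
    """Natural log of the RMS of each subspace's coefficients (16 values)."""
    out = []
    for s in p.subspaces:
        e = float(np.mean(s * s))
        out.append(_nan("log RMS undefined for zero-energy subspace") if e == 0.0 else 0.5 * math.log(e))
    return np.array(out)


def relative_energy(p: WaveletPacketCoeffs) -> np.ndarray:
    """Per-subspace energy divided by the total energy; sums to 1."""
    te = p.total_energy
    if te == 0.0:
        logger.warning("relative energy undefined for an all-zero window")
        return np.full(len(p.subspaces), np.nan)
    return p.energies / te


def nle(p: WaveletPacketCoeffs) -> np.ndarray:
    """Normalised log energy: log of (subspace energy / coefficients per subspace).

    Under periodization the coefficient count equals N/2^level exactly,
    so this is identically 2x the subspace log RMS.
    """
    out = []
    for s in p.subspaces:
        e = float(np.sum(s * s))
        out.append(_nan("NLE undefined for zero-energy subspace") if e == 0.0 else math.log(e / len(s)))
    return np.array(out)


# ---------------------------------------------------------------------------
# Block computation over a WindowSet
# ---------------------------------------------------------------------------

#: The 11 TFD feature blocks in canonical order (8 DWT statistics, 3 packet features).
TFD_BLOCKS = tuple(f"DWT{n}" for n in DWT_STATS) + ("LOGRMS", "RE", "NLE")


def tfd_block_arity(name: str, n_channels: int, level: int = 4) -> int:
    if name in ("LOGRMS", "RE", "NLE"):
        return (2**level) * n_channels
    if name in TFD_BLOCKS:
        return n_channels
    raise KeyError(name)


def compute_tfd_block(name: str, ws: WindowSet, cfg: WaveletConfig | None = None):
    """Compute one TFD feature block for every window; returns (values, columns)."""
    cfg = cfg or WaveletConfig()
    w, C = ws.n_windows, ws.n_channels
    ch = [f"ch{c + 1}" for c in range(C)]
    if name.startswith("DWT") and name[3:] in DWT_STATS:
        stat = name[3:]
        values = np.empty((w, C))
        for i in range(w):
            for c in range(C):
                values[i, c] = dwt_stats(dwt_level4(ws.windows[i, c], cfg))[stat]
        cols = [FeatureColumn(name, "value", c) for c in ch]
    elif name in ("LOGRMS", "RE", "NLE"):
        fn = {"LOGRMS": logrms, "RE": relative_energy, "NLE": nle}[name]
        nsub = 2**cfg.level
        values = np.empty((w, nsub * C))
        for i in range(w):
            for c in range(C):
                values[i, c * nsub : (c + 1) * nsub] = fn(wpt_level4(ws.windows[i, c], cfg))
        cols = [FeatureColumn(name, f"sub{p + 1}", c) for c in ch for p in range(nsub)]
    else:
        raise KeyError(f"unknown TFD block {name!r}")
    return values, tuple(cols)
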
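"""Feature assembly, named feature sets, sequential selection, and PCA.

``assemble`` concatenates any list of feature blocks (time, frequency,
time-frequency domains) into a :class:`~emgpr.signal_model.FeatureMatrix`
with a deterministic column order.  Named sets include the full per-domain
sets (``TD_ALL`` = 133 columns on 4 channels, ``FD_ALL`` = 828,
``TFD_ALL`` = 224), the proposed set ``FS`` (waveform length, power,
channel correlation and the Hjorth mobility/complexity parameters) and the
classic Hudgins set.

Sequential forward-selection / backward-elimination greedily adds blocks
that strictly improve a caller-supplied accuracy evaluator, then removes
kept blocks (in inverted order) whose removal does not hurt.  PCA reduces
any assembled matrix to its top principal components (default 20) after
z-score standardisation, fitted on training rows only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from . import features_fd as fd
from . import features_td as td
from . import features_tfd as tfd
from .signal_model import FeatureColumn, FeatureMatrix, WindowSet

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig", "FeatureSetSpec", "FEATURE_SETS", "ALL_BLOCKS",
    "assemble", "PCAProjection", "pca_fit", "pca_apply", "forward_backward_select",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureConfig:
    """Bundle of per-domain feature parameters."""

    thresholds: td.ThresholdConfig = field(default_factory=td.ThresholdConfig)
    bands: fd.BandConfig = field(default_factory=fd.BandConfig)
    wavelets: tfd.WaveletConfig = field(default_factory=tfd.WaveletConfig)


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named, ordered list of feature blocks."""

    name: str
    blocks: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [b for b in self.blocks if b not in ALL_BLOCKS]
        if unknown:
            raise ConfigError(f"unknown feature blocks {unknown}")


ALL_BLOCKS: tuple[str, ...] = td.TD_BLOCKS + fd.FD_BLOCKS + tfd.TFD_BLOCKS

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "TD_ALL": td.TD_BLOCKS,
    "FD_ALL": fd.FD_BLOCKS,
    "TFD_ALL": tfd.TFD_BLOCKS,
    "FS": ("WL", "VAR", "COR", "HMOB", "HCOM"),
    "HUDGINS": ("MAV", "WL", "SSC", "ZC", "DAMV"),
}


def resolve_blocks(features: str | list[str] | tuple[str, ...]) -> tuple[str, ...]:
    """Resolve a named set or an explicit block list to block names."""
    if isinstance(features, str):
        if features in FEATURE_SETS:
            return FEATURE_SETS[features]
        if features in ALL_BLOCKS:
            return (features,)
        raise ConfigError(f"unknown feature set or block {features!r}")
    out: list[str] = []
    for f in features:
        out.extend(resolve_blocks(f))
    return tuple(out)


def assemble(blocks, ws: WindowSet, cfg: FeatureConfig | None = None) -> FeatureMatrix:
    """Assemble the requested feature blocks over a window set.

    Column order is a pure function of the block list and channel count.
    """
    cfg = cfg or FeatureConfig()
    names = resolve_blocks(blocks)
    parts, cols = [], []
    for name in names:
        if name in td.TD_BLOCKS:
            v, c = td.compute_td_block(name, ws, cfg.thresholds)
        elif name in fd.FD_BLOCKS:
            v, c = fd.compute_fd_block(name, ws, cfg.bands)
        elif name in tfd.TFD_BLOCKS:
            v, c = tfd.compute_tfd_block(name, ws, cfg.wavelets)
        else:  # pragma: no cover - resolve_blocks already validates
            raise ConfigError(f"unknown block {name!r}")
        parts.append(v)
        cols.extend(c)
    values = np.hstack(parts) if parts else np.empty((ws.n_windows, 0))
    return FeatureMatrix(values, tuple(cols), ws.labels)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAProjection:
    """Z-score standardisation plus projection onto the top-m principal axes."""

    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # d x m, orthonormal columns
    m: int
    explained_variance: np.ndarray


def pca_fit(train: FeatureMatrix, m: int = 20) -> PCAProjection:
    """Fit the standardised PCA on training rows only."""
    X = train.values
    if X.shape[0] <= m:
        raise ValueError(f"need more than m={m} training rows, got {X.shape[0]}")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero = scale == 0
    if np.any(zero):
        logger.warning("%d zero-variance feature columns; scale 1 substituted", int(zero.sum()))
        scale = np.where(zero, 1.0, scale)
    Z = (X - center) / scale
    p = PCA(n_components=min(m, X.shape[1]), svd_solver="full")
    p.fit(Z)
    return PCAProjection(center, scale, p.components_.T, p.n_components_, p.explained_variance_)


def pca_apply(proj: PCAProjection, fm: FeatureMatrix) -> FeatureMatrix:
    """Project a feature matrix onto the fitted principal axes."""
    Z = (fm.values - proj.center) / proj.scale
    scores = Z @ proj.loadings
    cols = tuple(FeatureColumn("PCA", "score", f"pc{i + 1}") for i in range(proj.m))
    return FeatureMatrix(scores, cols, fm.labels)


# ---------------------------------------------------------------------------
# Sequential forward selection / backward elimination
# ---------------------------------------------------------------------------

def forward_backward_select(blocks, evaluator, baseline: float = 0.0) -> FeatureSetSpec:
    """Two-pass greedy feature-set selection.

    Pass 1 walks the candidate blocks in the given order and keeps a block
    iff adding it strictly increases the evaluator's accuracy.  Pass 2
    walks the kept blocks in inverted order and drops a block iff its
    removal does not decrease the accuracy.  ``baseline`` is the accuracy
    of the empty set (chance level, so the first informative block always
    enters).

    ``evaluator`` maps a block list to a cross-validated accuracy and must
    be deterministic for reproducible selections.
    """
    candidates = list(resolve_blocks(blocks))
    if not candidates:
        raise ConfigError("need at least one candidate block")

    selected: list[str] = []
    best = float(baseline)
    for b in candidates:
        acc = float(evaluator(selected + [b]))
        if acc > best:
            selected.append(b)
            best = acc

    for b in list(reversed(selected)):
        trial = [s for s in selected if s != b]
        acc = float(evaluator(trial)) if trial else float(baseline)
        if acc >= best:
            selected = trial
            best = acc

    if not selected:
        scores = [(float(evaluator([b])), b) for b in candidates]
        best_acc, best_block = max(scores, key=lambda t: t[0])
        logger.warning("selection came up empty; falling back to best single block %s (%.3f)", best_block, best_acc)
        selected = [best_block]
    return FeatureSetSpec("selected", tuple(selected))
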
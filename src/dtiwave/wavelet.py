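"""Multi-level DWT compression of sequence signal matrices.

Each of the six physicochemical channels is pushed through a 4-level
discrete wavelet transform: at every level the current approximation band
is split by the low-pass filter g into the next approximation band and by
the high-pass filter h into a detail band, with dyadic downsampling
(y[n] = sum_k x[k] f[2n - k]). The variable-length coefficient bands are
then compressed to a fixed-length descriptor: four order statistics
(max, min, mean, SD) per band per level, plus the leading DCT-II
coefficients of the approximation bands, which concentrate the smooth
low-frequency content the detail bands discard.

The mother wavelet is configurable; Daubechies-4 is the default. The
choice of wavelet, boundary mode and DCT scope are recorded in the
feature layout so runs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.fft import dct as _dct

from .errors import ConfigurationError, TooShortError
from .physchem import SequenceSignalMatrix

logger = logging.getLogger(__name__)

STAT_NAMES = ("max", "min", "mean", "sd")
BAND_NAMES = ("approx", "detail")


def min_length_for_levels(wavelet: str, levels: int, mode: str = "symmetric") -> int:
    """Smallest signal length admitting `levels` decompositions.

    For extension modes this is the boundary-dominance rule
    (filter_len - 1) * 2**levels; periodic wrapping has no extension, so
    only the halving itself limits depth (2**levels).
    """
    if mode == "periodization":
        return 2**levels
    flen = pywt.Wavelet(wavelet).dec_len
    return (flen - 1) * 2**levels


def max_feasible_levels(length: int, wavelet: str, mode: str = "symmetric") -> int:
    if mode == "periodization":
        return max(0, int(np.floor(np.log2(length))))
    flen = pywt.Wavelet(wavelet).dec_len
    return pywt.dwt_max_level(length, flen)


@dataclass(frozen=True)
class WaveletConfig:
    """Tunable knobs of the target featurizer.

    n_dct leading DCT coefficients are taken per approximation band;
    dct_scope 'all' uses every level's approximation band, 'last' only the
    deepest. stat_ddof is the SD convention for band statistics (sample SD
    by default).
    """

    wavelet: str = "db4"
    levels: int = 4
    mode: str = "symmetric"
    n_dct: int = 5
    dct_scope: str = "all"
    stat_ddof: int = 1
    short_sequence_fallback: bool = True

    def __post_init__(self):
        if self.dct_scope not in ("all", "last"):
            raise ConfigurationError(f"dct_scope must be 'all' or 'last', got {self.dct_scope!r}")
        if self.levels < 1 or self.n_dct < 1:
            raise ConfigurationError("levels and n_dct must be >= 1")


@dataclass
class WaveletDecomposition:
    """Per-level approximation/detail coefficient bands of one channel."""

    approx: list[np.ndarray]  # approx[l-1] = level-l approximation band
    detail: list[np.ndarray]
    wavelet_name: str
    levels: int
    mode: str


def dwt_decompose(
    signal: np.ndarray,
    wavelet: str = "db4",
    levels: int = 4,
    mode: str = "symmetric",
) -> WaveletDecomposition:
    """Cascade DWT of a 1-D signal: each level refilters the previous
    approximation band only (the classic decomposition tree).

    Raises :class:`TooShortError` when the signal does not admit the
    requested depth for the chosen filter length.
    """
    x = np.asarray(signal, dtype=float).ravel()
    feasible = max_feasible_levels(x.size, wavelet, mode)
    if levels > feasible:
        raise TooShortError(x.size, levels, min_length_for_levels(wavelet, levels, mode))
    approx: list[np.ndarray] = []
    detail: list[np.ndarray] = []
    current = x
    for _ in range(levels):
        cA, cD = pywt.dwt(current, wavelet, mode=mode)
        approx.append(cA)
        detail.append(cD)
        current = cA
    return WaveletDecomposition(
        approx=approx, detail=detail, wavelet_name=wavelet, levels=levels, mode=mode
    )


def dwt_reconstruct(decomp: WaveletDecomposition, length: int) -> np.ndarray:
    """Invert the cascade (used by round-trip tests)."""
    current = decomp.approx[-1]
    for level in range(decomp.levels, 0, -1):
        cD = decomp.detail[level - 1]
        current = pywt.idwt(current, cD, decomp.wavelet_name, mode=decomp.mode)
        want = decomp.approx[level - 2].size if level > 1 else length
        current = current[:want]
    return current


def band_statistics(band: np.ndarray, ddof: int = 1) -> np.ndarray:
    """(max, min, mean, SD) of one coefficient band, in that fixed order.

    A single-coefficient band has SD 0 by convention.
    """
    band = np.asarray(band, dtype=float)
    if band.size == 0:
        raise ConfigurationError("empty coefficient band")
    sd = 0.0 if band.size <= ddof else float(band.std(ddof=ddof))
    return np.array([band.max(), band.min(), band.mean(), sd])


def dct_head(coeffs: np.ndarray, n: int = 5) -> np.ndarray:
    """First n orthonormal DCT-II coefficients, zero-padded if the band is
    shorter than n (keeps the feature vector length fixed)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size == 0 or n < 1:
        raise ConfigurationError("dct_head requires a non-empty band and n >= 1")
    head = _dct(coeffs, type=2, norm="ortho")[:n]
    if head.size < n:
        logger.warning("band of length %d zero-padded to %d DCT coefficients", coeffs.size, n)
        head = np.pad(head, (0, n - head.size))
    return head


@dataclass(frozen=True)
class FeatureLayout:
    """Bijection between feature-vector indices and (channel, level, band,
    statistic/DCT-coefficient) labels."""

    labels: tuple[str, ...]
    config: WaveletConfig = field(default_factory=WaveletConfig)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def feature_layout(config: WaveletConfig | None = None, n_channels: int = 6) -> FeatureLayout:
    """Label every index of the target feature vector.

    Default geometry: 6 channels x 4 levels x 2 bands x 4 statistics = 192
    statistic features plus 6 x 4 x 5 = 120 DCT features, 312 in total.
    """
    config = config or WaveletConfig()
    labels: list[str] = []
    for ch in range(1, n_channels + 1):
        for level in range(1, config.levels + 1):
            for band in BAND_NAMES:
                for stat in STAT_NAMES:
                    labels.append(f"ch{ch}.L{level}.{band}.{stat}")
    dct_levels = range(1, config.levels + 1) if config.dct_scope == "all" else (config.levels,)
    for ch in range(1, n_channels + 1):
        for level in dct_levels:
            for k in range(config.n_dct):
                labels.append(f"ch{ch}.L{level}.approx.dct{k}")
    return FeatureLayout(labels=tuple(labels), config=config)


@dataclass(frozen=True)
class TargetFeatureVector:
    """Fixed-length wavelet descriptor of one target sequence."""

    values: np.ndarray
    layout: FeatureLayout
    sequence_id: str = ""

    def __len__(self) -> int:
        return self.values.size


def target_features(
    matrix: SequenceSignalMatrix,
    config: WaveletConfig | None = None,
) -> TargetFeatureVector:
    """Compress an L x 6 signal matrix into the fixed-length descriptor.

    Sequences too short for the configured depth fall back to the deepest
    feasible decomposition; the missing levels' features are zero-filled so
    the feature matrix stays rectangular (logged).
    """
    config = config or WaveletConfig()
    layout = feature_layout(config, n_channels=matrix.values.shape[1])
    L = matrix.values.shape[0]
    depth = config.levels
    feasible = max_feasible_levels(L, config.wavelet)
    if feasible < depth:
        if not config.short_sequence_fallback:
            raise TooShortError(L, depth, min_length_for_levels(config.wavelet, depth))
        depth = feasible
        logger.warning(
            "sequence %s (length %d) supports %d of %d levels; missing bands zero-filled",
            matrix.sequence_id, L, depth, config.levels,
        )

    n_channels = matrix.values.shape[1]
    values = np.zeros(len(layout))
    pos = 0
    decomps: list[WaveletDecomposition | None] = []
    for ch in range(n_channels):
        decomp = (
            dwt_decompose(matrix.values[:, ch], config.wavelet, depth, config.mode)
            if depth >= 1
            else None
        )
        decomps.append(decomp)
        for level in range(1, config.levels + 1):
            for band_name in BAND_NAMES:
                if decomp is not None and level <= depth:
                    band = (decomp.approx if band_name == "approx" else decomp.detail)[level - 1]
                    values[pos : pos + 4] = band_statistics(band, ddof=config.stat_ddof)
                pos += 4
    dct_levels = range(1, config.levels + 1) if config.dct_scope == "all" else (config.levels,)
    for ch in range(n_channels):
        decomp = decomps[ch]
        for level in dct_levels:
            if decomp is not None and level <= depth:
                values[pos : pos + config.n_dct] = dct_head(
                    decomp.approx[level - 1], config.n_dct
                )
            pos += config.n_dct
    assert pos == len(layout)
    return TargetFeatureVector(values=values, layout=layout, sequence_id=matrix.sequence_id)


def featurize_targets(
    matrices: dict[str, SequenceSignalMatrix],
    config: WaveletConfig | None = None,
) -> dict[str, TargetFeatureVector]:
    config = config or WaveletConfig()
    return {tid: target_features(m, config) for tid, m in matrices.items()}
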
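"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the code paths they check: the DWT
oracle is an explicit convolve-and-downsample filter bank, the DCT oracle
a literal basis-matrix product, and the AUC oracle the Mann-Whitney
rank-statistic form.
"""

from __future__ import annotations

import numpy as np
import pytest
import pywt

import dtiwave as dw


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def symmetric_extend(x: np.ndarray, pad: int) -> np.ndarray:
    """Half-point symmetric extension by `pad` samples each side, with
    repeated reflection so arbitrarily short signals are handled."""
    n = len(x)
    idx = np.mod(np.arange(-pad, n + pad), 2 * n)
    idx = np.where(idx >= n, 2 * n - 1 - idx, idx)
    return np.asarray(x, float)[idx]


def dwt_single_level_oracle(x, dec_lo, dec_hi):
    """One filter-bank level computed as y[n] = sum_k x_ext[k] f[2n - k]:
    explicit convolution with the analysis filters followed by dyadic
    downsampling, under half-point symmetric extension."""
    x = np.asarray(x, float)
    flen = len(dec_lo)
    pad = flen - 1
    ext = symmetric_extend(x, pad)
    out_len = (len(x) + flen - 1) // 2
    approx = np.zeros(out_len)
    detail = np.zeros(out_len)
    for n in range(out_len):
        # output sample n draws on ext samples 2n+1 ... 2n+flen (0-based in ext)
        window = ext[2 * n + 1 : 2 * n + 1 + flen]
        approx[n] = np.dot(window, dec_lo[::-1])
        detail[n] = np.dot(window, dec_hi[::-1])
    return approx, detail


def dwt_cascade_oracle(x, wavelet_name: str, levels: int):
    """Multi-level decomposition: refilter the approximation band only."""
    w = pywt.Wavelet(wavelet_name)
    dec_lo = np.asarray(w.dec_lo)
    dec_hi = np.asarray(w.dec_hi)
    approx_bands, detail_bands = [], []
    current = np.asarray(x, float)
    for _ in range(levels):
        a, d = dwt_single_level_oracle(current, dec_lo, dec_hi)
        approx_bands.append(a)
        detail_bands.append(d)
        current = a
    return approx_bands, detail_bands


def dct_matrix(n: int) -> np.ndarray:
    """Orthonormal DCT-II basis matrix (rows are basis vectors)."""
    k = np.arange(n)[:, None]
    m = np.arange(n)[None, :]
    basis = np.cos(np.pi * k * (2 * m + 1) / (2 * n))
    basis *= np.sqrt(2.0 / n)
    basis[0] /= np.sqrt(2.0)
    return basis


def mann_whitney_auc(y_true, scores) -> float:
    """AUC as the normalized Mann-Whitney U statistic (tie-free scores)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, float)
    pos = scores[y_true == 1]
    neg = scores[y_true != 1]
    wins = sum(np.sum(p > neg) + 0.5 * np.sum(p == neg) for p in pos)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def table():
    return dw.default_table()


@pytest.fixture(scope="session")
def small_bench():
    """A quick planted-signal benchmark shared by model-level tests."""
    return dw.synthesize_benchmark(
        n_drugs=30, n_targets=20, n_edges=80, signal_strength=1.0, seed=7
    )


@pytest.fixture(scope="session")
def small_bench_features(small_bench, table):
    feats = {
        tid: dw.target_features(dw.encode_sequence(seq, table, tid))
        for tid, seq in small_bench.sequences.items()
    }
    return feats
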
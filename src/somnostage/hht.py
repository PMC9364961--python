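"""Empirical mode decomposition and Hilbert instantaneous-frequency analysis.

Sleep EEG is non-stationary and multi-component, so Fourier band powers blur
the time-local rhythm structure.  EMD adaptively splits a signal into a
small number of intrinsic mode functions (IMFs) — near-mono-component
oscillations ordered from fastest to slowest — after which the Hilbert
transform assigns each IMF a well-defined instantaneous frequency (the
derivative of the analytic-signal phase).  Pooling the instantaneous
frequencies of the first few IMFs per sleep stage and histogramming them
gives a compact per-stage frequency signature.

The sifting loop here is the classic algorithm: cubic-spline envelopes
through the maxima and minima (mirror-extended at the ends), mean-envelope
subtraction iterated until a Cauchy-style SD criterion falls below
threshold and the candidate satisfies the IMF extrema/zero-crossing
property, then the IMF is removed and sifting restarts on the remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert, periodogram

from .stages import StageLabel
from .synth import EpochRecord

__all__ = [
    "IMFSet",
    "InstFreqSeries",
    "FreqHistogram",
    "emd",
    "instantaneous_frequency",
    "stage_frequency_histograms",
    "relative_band_energy",
]

logger = logging.getLogger(__name__)

#: Default histogram support: the clinically considered 0.5-30 Hz EEG band,
#: extended down to 0 Hz so clamped low-frequency mass is representable.
DEFAULT_HIST_RANGE = (0.0, 30.0)
DEFAULT_HIST_BINS = 50


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus residual for one signal."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    fs_hz: float

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out

    def __len__(self) -> int:
        return len(self.imfs)


@dataclass
class InstFreqSeries:
    """Instantaneous-frequency samples (Hz) of one IMF, edges trimmed."""

    values: np.ndarray
    source_imf_index: int
    n_clamped: int = 0  # negative-frequency samples clamped to 0
    degenerate: bool = False  # all-zero source IMF


@dataclass
class FreqHistogram:
    """Normalized probability-density histogram over frequency bins."""

    bin_edges: np.ndarray
    densities: np.ndarray

    def integral(self) -> float:
        return float(np.sum(self.densities * np.diff(self.bin_edges)))


def _extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima (plateaus take their midpoint)."""
    dx = np.diff(x)
    # collapse exact plateaus so flat tops register one extremum
    nz = np.nonzero(dx)[0]
    if nz.size < 2:
        return np.array([], int), np.array([], int)
    signs = np.sign(dx[nz])
    flips = np.nonzero(signs[1:] != signs[:-1])[0]
    maxima, minima = [], []
    for k in flips:
        left, right = nz[k], nz[k + 1]
        idx = (left + right + 1) // 2
        if signs[k] > 0:
            maxima.append(idx)
        else:
            minima.append(idx)
    return np.asarray(maxima, int), np.asarray(minima, int)


def _count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def _mirrored_envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extending 2 at each end."""
    t = idx.astype(float)
    v = x[idx]
    k = min(2, idx.size - 1)
    # mirror about the first/last sample positions
    left_t = -t[1:k + 1][::-1]
    left_v = v[1:k + 1][::-1]
    right_t = 2 * (n - 1) - t[-k - 1:-1][::-1]
    right_v = v[-k - 1:-1][::-1]
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    order = np.argsort(tt)
    tt, vv = tt[order], vv[order]
    keep = np.concatenate([[True], np.diff(tt) > 0])
    spline = CubicSpline(tt[keep], vv[keep])
    return spline(np.arange(n, dtype=float))


def _is_imf(candidate: np.ndarray) -> bool:
    mx, mn = _extrema_indices(candidate)
    n_ext = mx.size + mn.size
    return abs(n_ext - _count_zero_crossings(candidate)) <= 1


def emd(
    signal: np.ndarray,
    fs_hz: float,
    max_imfs: int = 8,
    stop_sd: float = 0.2,
    max_siftings: int = 50,
) -> IMFSet:
    """Decompose a signal into intrinsic mode functions by sifting.

    Sifting on each mode iterates mean-envelope subtraction until the
    Cauchy SD statistic ``sum((h_prev - h)^2) / sum(h_prev^2)`` drops below
    ``stop_sd`` and the candidate satisfies the IMF property
    (|#extrema - #zero-crossings| <= 1), or ``max_siftings`` is reached.
    Decomposition stops at ``max_imfs`` or when the remainder is monotone
    (fewer than two maxima or two minima).  The IMFs plus residual
    reconstruct the input exactly (each IMF is literally subtracted).
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("emd expects a 1-D signal")
    if x.size < 16:
        raise ValueError("signal too short for envelope interpolation (need >= 16)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")

    imfs: list[np.ndarray] = []
    residual = x.copy()
    scale = float(np.max(np.abs(x))) or 1.0
    for _ in range(max_imfs):
        mx, mn = _extrema_indices(residual)
        if mx.size < 2 or mn.size < 2:
            break  # monotone / trend remainder
        h = residual.copy()
        for _ in range(max_siftings):
            mx, mn = _extrema_indices(h)
            if mx.size < 2 or mn.size < 2:
                break
            upper = _mirrored_envelope(h, mx, h.size)
            lower = _mirrored_envelope(h, mn, h.size)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = float(np.sum(h * h))
            sd = float(np.sum(mean_env * mean_env)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < stop_sd and _is_imf(h):
                break
        if float(np.max(np.abs(h))) < 1e-12 * scale:
            break  # numerically nothing left to extract
        imfs.append(h)
        residual = residual - h
    return IMFSet(imfs=imfs, residual=residual, fs_hz=fs_hz)


def instantaneous_frequency(
    imf: np.ndarray,
    fs_hz: float,
    trim_fraction: float = 0.05,
    source_imf_index: int = 0,
) -> InstFreqSeries:
    """Hilbert instantaneous frequency of a (near-mono-component) IMF.

    The analytic signal's unwrapped phase is differentiated and scaled by
    fs / 2*pi; ``trim_fraction`` of samples is dropped at each end where the
    Hilbert transform has edge artefacts.  Negative frequencies (phase
    unwrapping noise) are clamped to zero and counted.
    """
    x = np.asarray(imf, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected a 1-D IMF")
    if not np.any(x):
        return InstFreqSeries(values=np.array([]),
                              source_imf_index=source_imf_index,
                              degenerate=True)
    phase = np.unwrap(np.angle(hilbert(x)))
    freq = np.gradient(phase) * fs_hz / (2.0 * np.pi)
    n_trim = int(np.floor(trim_fraction * freq.size))
    if n_trim > 0:
        freq = freq[n_trim:-n_trim]
    n_clamped = int(np.count_nonzero(freq < 0))
    freq = np.maximum(freq, 0.0)
    return InstFreqSeries(values=freq, source_imf_index=source_imf_index,
                          n_clamped=n_clamped)


def stage_frequency_histograms(
    epochs: Sequence[EpochRecord],
    n_imfs: int = 4,
    bins: int = DEFAULT_HIST_BINS,
    *,
    hist_range: tuple[float, float] = DEFAULT_HIST_RANGE,
    channel: int = 0,
    max_imfs: int = 8,
) -> dict[StageLabel, list[FreqHistogram]]:
    """Per-stage probability-density histograms of IMF instantaneous frequency.

    For every stage present in ``epochs``, the EEG channel of each of its
    epochs is EMD-decomposed; the instantaneous-frequency samples of IMF
    k (k = 1..n_imfs) are pooled across that stage's epochs and binned into
    a normalized density histogram, one histogram per IMF index.  Stages
    with no epochs are omitted (with a logged notice).  Samples that were
    clamped from negative values are excluded from the pools.
    """
    if len(epochs) == 0:
        raise ValueError("need at least one epoch")
    pools: dict[StageLabel, list[list[np.ndarray]]] = {}
    for rec in epochs:
        sig = rec.samples[:, channel]
        modes = emd(sig, rec.fs_hz, max_imfs=max_imfs)
        per_stage = pools.setdefault(rec.stage, [[] for _ in range(n_imfs)])
        for k in range(min(n_imfs, len(modes))):
            series = instantaneous_frequency(modes.imfs[k], rec.fs_hz,
                                             source_imf_index=k)
            if series.degenerate:
                continue
            values = series.values
            if series.n_clamped:
                values = values[values > 0.0]
            per_stage[k].append(values)

    for stage in StageLabel:
        if stage not in pools:
            logger.info("stage %s has no epochs; omitted from histograms",
                        stage.name)

    out: dict[StageLabel, list[FreqHistogram]] = {}
    edges = np.linspace(hist_range[0], hist_range[1], bins + 1)
    for stage, per_imf in pools.items():
        hists = []
        for k in range(n_imfs):
            pooled = (np.concatenate(per_imf[k]) if per_imf[k]
                      else np.array([]))
            if pooled.size == 0:
                densities = np.zeros(bins)
            else:
                densities, _ = np.histogram(pooled, bins=edges, density=True)
                total = float(np.sum(densities * np.diff(edges)))
                if total > 0:  # renormalize mass falling outside the range
                    densities = densities / total
            hists.append(FreqHistogram(bin_edges=edges.copy(), densities=densities))
        out[stage] = hists
    return out


def relative_band_energy(
    signal: np.ndarray,
    fs_hz: float,
    bands: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Periodogram band powers normalized over the union of the bands.

    Returns one fraction per band; the fractions sum to 1.  Rejects
    zero-power signals and bands outside (0, fs/2].
    """
    x = np.asarray(signal, dtype=np.float64)
    for lo, hi in bands:
        if not (0 <= lo < hi <= fs_hz / 2.0):
            raise ValueError(f"band ({lo}, {hi}) outside (0, fs/2] at fs={fs_hz}")
    freqs, psd = periodogram(x, fs=fs_hz)
    powers = np.array(
        [float(np.sum(psd[(freqs >= lo) & (freqs < hi)])) for lo, hi in bands]
    )
    total = powers.sum()
    if total <= 0:
        raise ValueError("signal has zero power in the requested bands")
    return powers / total
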
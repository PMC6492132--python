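"""Temporal filtering and power-spectral-density estimation for node time series.

Filtering is zero-phase (forward-backward) Butterworth of prototype order 4 by
default, applied per node.  Because the filter runs forward and backward, the
effective magnitude response is |H(f)|^2 where H is the single-pass transfer
function; all gain contracts in this module are stated for the single pass.

PSD estimation follows Welch's overlapped segment averaging with at most eight
segments at 50% overlap (segment length floor(T/4.5)), Hamming window, per-
segment mean removal, one-sided density normalization so that the rectangle-rule
integral over frequency approximates the series variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

#: The four non-overlapping analysis bands (Hz) tiling [0.005, 0.385] Hz.
CANONICAL_BANDS: tuple[tuple[float, float], ...] = (
    (0.005, 0.096),
    (0.096, 0.182),
    (0.182, 0.298),
    (0.298, 0.385),
)

#: Very-low-frequency drift cutoff (Hz); the "no filtering" pipeline applies
#: only a high-pass at this cutoff.
DRIFT_CUTOFF_HZ: float = 0.005


@dataclass(frozen=True)
class FilterSpec:
    """Specification of a Butterworth filter.

    Parameters
    ----------
    kind : {"highpass", "bandpass"}
    cutoffs_hz : tuple of float
        One cutoff for highpass, (low, high) for bandpass, strictly inside
        (0, Nyquist).
    sampling_rate : float
        Sampling rate in Hz (1/TR for fMRI).
    order : int
        Prototype filter order (a bandpass therefore has 2*order poles).
    """

    kind: str
    cutoffs_hz: tuple[float, ...]
    sampling_rate: float
    order: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        cut = tuple(float(c) for c in self.cutoffs_hz)
        object.__setattr__(self, "cutoffs_hz", cut)
        n_expected = 1 if self.kind == "highpass" else 2
        if len(cut) != n_expected:
            raise ValueError(f"{self.kind} needs {n_expected} cutoff(s), got {len(cut)}")
        if self.order < 1:
            raise ValueError("order must be a positive integer")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        nyq = self.nyquist
        for c in cut:
            if not 0 < c < nyq:
                raise ValueError(
                    f"cutoff {c} Hz outside (0, Nyquist={nyq:.6g}) for "
                    f"fs={self.sampling_rate} Hz"
                )
        if self.kind == "bandpass" and not cut[0] < cut[1]:
            raise ValueError("bandpass requires low < high cutoff")

    @property
    def nyquist(self) -> float:
        return self.sampling_rate / 2.0


def canonical_band_specs(sampling_rate: float, order: int = 4) -> list[FilterSpec]:
    """The four canonical band-pass specs at a given sampling rate.

    The top edge of the highest band (0.385 Hz) sits within 0.1% of the
    Nyquist frequency at TR = 1.3 s; a top edge within 1% of Nyquist is
    clipped to 0.999*Nyquist so the band remains designable.
    """
    nyq = sampling_rate / 2.0
    specs = []
    for low, high in CANONICAL_BANDS:
        if high >= nyq:
            if high <= 1.01 * nyq:
                high = 0.999 * nyq
            # else: leave as-is and let FilterSpec raise
        specs.append(FilterSpec("bandpass", (low, high), sampling_rate, order))
    return specs


def design_butterworth(spec: FilterSpec) -> np.ndarray:
    """Design the Butterworth filter as second-order sections.

    The single-pass magnitude response at each cutoff is 1/sqrt(2).
    """
    btype = "highpass" if spec.kind == "highpass" else "bandpass"
    wn = spec.cutoffs_hz[0] if spec.kind == "highpass" else list(spec.cutoffs_hz)
    return signal.butter(spec.order, wn, btype=btype, fs=spec.sampling_rate, output="sos")


def frequency_response(spec: FilterSpec, freqs_hz: np.ndarray) -> np.ndarray:
    """Complex single-pass frequency response H(f) at the given frequencies."""
    sos = design_butterworth(spec)
    _, h = signal.sosfreqz(sos, worN=np.asarray(freqs_hz, dtype=float), fs=spec.sampling_rate)
    return h


def _padlen(spec: FilterSpec) -> int:
    # odd-reflection padding of 3x the prototype order at both ends
    return 3 * spec.order


def filter_series(ts: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase (forward-backward) filtering along the last axis.

    Effective attenuation is |H|^2; no phase distortion, so lag structure of
    jointly filtered channels is preserved.
    """
    ts = np.asarray(ts, dtype=float)
    padlen = _padlen(spec)
    if ts.shape[-1] <= 3 * spec.order:
        raise ValueError(
            f"series length {ts.shape[-1]} too short for order-{spec.order} "
            f"zero-phase filtering (need > {3 * spec.order})"
        )
    sos = design_butterworth(spec)
    return signal.sosfiltfilt(sos, ts, axis=-1, padtype="odd", padlen=padlen)


def band_power_fraction(spec: FilterSpec, n_grid: int = 8192) -> float:
    """Mean zero-phase power transfer |H(f)|^4 over [0, Nyquist].

    White noise of unit variance filtered forward-backward retains this
    fraction of its variance; a covariance matrix of jointly filtered channels
    is scaled by the same factor.
    """
    freqs = np.linspace(0.0, spec.nyquist, n_grid)
    h = frequency_response(spec, freqs)
    return float(np.mean(np.abs(h) ** 4))


@dataclass(frozen=True)
class PsdEstimate:
    """One-sided Welch PSD per node."""

    frequencies: np.ndarray  # Hz, 0..Nyquist, monotone
    power: np.ndarray  # (n_nodes, n_freqs), >= 0
    n_segments: int
    segment_length: int
    overlap_fraction: float

    def integral(self) -> np.ndarray:
        """Rectangle-rule integral over frequency per node (approximates variance)."""
        df = float(self.frequencies[1] - self.frequencies[0])
        return self.power.sum(axis=-1) * df

    def to_frame(self):
        """Tidy (frequency, node, power) table."""
        import pandas as pd

        n_nodes, n_freqs = self.power.shape
        return pd.DataFrame({
            "frequency": np.tile(self.frequencies, n_nodes),
            "node": np.repeat(np.arange(n_nodes), n_freqs),
            "power": self.power.ravel(),
        })


def welch_psd(ts: np.ndarray, sampling_rate: float) -> PsdEstimate:
    """Welch PSD with at most eight segments at 50% overlap, Hamming window."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    n_time = ts.shape[-1]
    if n_time < 16:
        raise ValueError(f"series length {n_time} < 16: too short for Welch estimation")
    nperseg = max(8, int(n_time / 4.5))
    noverlap = nperseg // 2
    freqs, power = signal.welch(
        ts,
        fs=sampling_rate,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    n_segments = 1 + (n_time - nperseg) // (nperseg - noverlap)
    return PsdEstimate(
        frequencies=freqs,
        power=power,
        n_segments=int(n_segments),
        segment_length=nperseg,
        overlap_fraction=noverlap / nperseg,
    )


class ButterworthFilter(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying zero-phase Butterworth filtering.

    Operates on a single node-by-time matrix or a stack of samples
    (n_samples, n_nodes, n_time); stateless, ``fit`` is a no-op.
    """

    def __init__(
        self,
        kind: str = "highpass",
        cutoffs_hz: Sequence[float] = (DRIFT_CUTOFF_HZ,),
        sampling_rate: float = 1.0 / 1.3,
        order: int = 4,
    ):
        self.kind = kind
        self.cutoffs_hz = cutoffs_hz
        self.sampling_rate = sampling_rate
        self.order = order

    def _spec(self) -> FilterSpec:
        return FilterSpec(self.kind, tuple(self.cutoffs_hz), self.sampling_rate, self.order)

    def fit(self, X, y=None):
        self._spec()  # validate
        self.n_features_in_ = 0
        return self

    def transform(self, X) -> np.ndarray:
        return filter_series(np.asarray(X, dtype=float), self._spec())
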
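"""Cross-spectra and lagged linear connectivity between ROI pairs.

The cross-spectrum ``S(f)`` is estimated by averaging Hann-tapered DFT
outer products over epochs.  From it, the lagged linear connectivity of
a channel pair (x, y) at frequency f is the lagged squared coherence

    rho2_lag(f) = Im(S_xy)^2 / (S_xx S_yy - Re(S_xy)^2),

the part of the linear dependence attributable to a non-zero phase lag.
Purely instantaneous (volume-conduction-like) mixing contributes only to
``Re(S_xy)`` and is cancelled by construction — the defining property of
the measure.  Band values are the unweighted mean of per-bin values over
bins with ``lo <= f < hi``.  The alternative export ``lagged_F`` is the
monotone transform ``-ln(1 - rho2_lag)`` averaged the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bands import CANONICAL_BANDS, BandSpec
from .errors import InvalidBandError, InvalidSpecError
from .recording import EpochedRecording

__all__ = [
    "CrossSpectrum",
    "ConnectivityMatrix",
    "estimate_cross_spectrum",
    "lagged_connectivity",
    "connectivity_stack",
    "epoch_shuffle_surrogate",
    "surrogate_distribution",
]

_LOG_CLIP_EPS = 1e-12


@dataclass
class CrossSpectrum:
    """Epoch-averaged cross-spectral matrices.

    ``S`` has shape ``(n_freqs, n_channels, n_channels)``; ``S[k]`` is
    Hermitian with a real nonnegative diagonal (the power spectra).
    """

    freqs: np.ndarray
    S: np.ndarray
    n_epochs_averaged: int
    taper: str = "hann"

    @property
    def n_channels(self) -> int:
        return self.S.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative band-aggregated connectivity, zero diagonal."""

    subject_id: str
    band: BandSpec
    W: np.ndarray
    measure: str = "lagged_r2"
    meta: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path, roi_labels: Sequence[str]) -> Path:
        path = Path(path)
        pd.DataFrame(self.W, index=list(roi_labels), columns=list(roi_labels)).to_csv(
            path, sep="\t", float_format="%.10g"
        )
        return path


def estimate_cross_spectrum(
    rec: EpochedRecording, window: str = "hann"
) -> CrossSpectrum:
    """Estimate the cross-spectrum by epoch-averaged tapered periodograms.

    The frequency resolution is ``fs / samples_per_epoch`` (0.5 Hz for
    2 s epochs).  With a single epoch the estimate is rank one and
    lagged coherence is degenerate; a warning is issued.
    """
    if rec.n_epochs < 1:
        raise InvalidSpecError("cannot estimate a cross-spectrum without epochs")
    if rec.n_epochs < 2:
        warnings.warn(
            "single-epoch cross-spectrum is rank-deficient; "
            "lagged coherence is degenerate",
            stacklevel=2,
        )
    spe = rec.samples_per_epoch
    if window == "hann":
        w = np.hanning(spe)
    elif window in ("boxcar", "rect", "none"):
        w = np.ones(spe)
    else:
        raise InvalidSpecError(f"unknown taper {window!r}")
    X = np.fft.rfft(rec.data * w, axis=-1)  # (epochs, channels, freqs)
    # Welch-style scaling; connectivity ratios are scale-invariant anyway.
    norm = rec.n_epochs * rec.fs * (w**2).sum()
    S = np.einsum("eif,ejf->fij", X, X.conj()) / norm
    freqs = np.fft.rfftfreq(spe, d=1.0 / rec.fs)
    return CrossSpectrum(freqs=freqs, S=S, n_epochs_averaged=rec.n_epochs, taper=window)


def _lagged_r2_bins(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin lagged squared coherence for a (n_bins, n, n) spectral stack.

    Returns the per-bin pairwise values and a validity mask; bins whose
    denominator is non-positive for a pair (numerically degenerate) are
    masked out.
    """
    n = S.shape[1]
    P = np.real(np.einsum("fii->fi", S))  # power spectra, (bins, n)
    den = P[:, :, None] * P[:, None, :] - np.real(S) ** 2
    num = np.imag(S) ** 2
    valid = den > 0
    # the diagonal denominator is identically zero; the self-pair value is 0
    # by convention, not a degenerate bin
    valid |= np.eye(n, dtype=bool)
    r2 = np.zeros_like(den)
    np.divide(num, den, out=r2, where=den > 0)
    return r2, valid


def lagged_connectivity(
    cs: CrossSpectrum,
    band: BandSpec,
    measure: str = "lagged_r2",
    subject_id: str = "unknown",
) -> ConnectivityMatrix:
    """Band-aggregated lagged linear connectivity between all pairs.

    Per pair, the band value is the mean over in-band bins of
    ``rho2_lag`` (``measure="lagged_r2"``) or of ``-ln(1 - rho2_lag)``
    (``measure="lagged_F"``).  Values are clipped to ``[0, 1 - 1e-12]``
    before the log; the diagonal is forced to zero.
    """
    if measure not in ("lagged_r2", "lagged_F"):
        raise InvalidSpecError(f"unknown measure {measure!r}")
    nyq = cs.freqs[-1]
    if band.lo >= nyq:
        raise InvalidBandError(
            f"band {band.name} [{band.lo}, {band.hi}) outside [0, {nyq}) Hz"
        )
    mask = band.contains(cs.freqs)
    if not mask.any():
        raise InvalidBandError(
            f"band {band.name} [{band.lo}, {band.hi}) contains no frequency bins"
        )
    r2, valid = _lagged_r2_bins(cs.S[mask])
    n_skipped = int(valid.size - valid.sum())
    if n_skipped:
        warnings.warn(
            f"band {band.name}: skipped {n_skipped} bin/pair value(s) with "
            "non-positive denominator",
            stacklevel=2,
        )
    r2 = np.clip(r2, 0.0, 1.0 - _LOG_CLIP_EPS)
    vals = -np.log1p(-r2) if measure == "lagged_F" else r2
    counts = valid.sum(axis=0)
    W = np.zeros(counts.shape)
    np.divide(
        np.where(valid, vals, 0.0).sum(axis=0),
        counts,
        out=W,
        where=counts > 0,
    )
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return ConnectivityMatrix(
        subject_id=subject_id,
        band=band,
        W=W,
        measure=measure,
        meta={
            "n_epochs": cs.n_epochs_averaged,
            "taper": cs.taper,
            "band_lo": band.lo,
            "band_hi": band.hi,
            "n_bins": int(mask.sum()),
        },
    )


def connectivity_stack(
    rec: EpochedRecording,
    bands: Iterable[BandSpec] = CANONICAL_BANDS,
    measure: str = "lagged_r2",
    window: str = "hann",
) -> dict[str, ConnectivityMatrix]:
    """One connectivity matrix per band for a subject."""
    cs = estimate_cross_spectrum(rec, window=window)
    return {
        band.name: lagged_connectivity(cs, band, measure, subject_id=rec.subject_id)
        for band in bands
    }


def epoch_shuffle_surrogate(
    rec: EpochedRecording, rng: np.random.Generator
) -> EpochedRecording:
    """Destroy cross-channel dependence by shuffling epochs per channel.

    Each channel's epochs are independently permuted, which preserves
    every channel's spectrum exactly while breaking the epoch pairing
    that carries between-channel dependence — the chance-floor null for
    lagged connectivity.
    """
    data = rec.data.copy()
    for ch in range(rec.n_rois):
        data[:, ch, :] = data[rng.permutation(rec.n_epochs), ch, :]
    return rec.with_data(data)


def surrogate_distribution(
    rec: EpochedRecording,
    band: BandSpec,
    n_surrogates: int = 100,
    measure: str = "lagged_r2",
    seed: int = 0,
) -> np.ndarray:
    """Pooled off-diagonal connectivity values from epoch-shuffled surrogates.

    The empirical quantiles of the returned sample estimate the chance
    floor of the measure for this recording and band.
    """
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(rec.n_rois, k=1)
    out = []
    for _ in range(n_surrogates):
        sur = epoch_shuffle_surrogate(rec, rng)
        cs = estimate_cross_spectrum(sur)
        out.append(lagged_connectivity(cs, band, measure).W[iu])
    return np.concatenate(out)
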
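"""Alpha amplitude by zero-padded FFT, IAF estimation, and Gabor phase.

Amplitude scaling follows the 2/N single-sided convention (N = epoch
length before zero-padding), so a unit sinusoid at a bin centre in an
untapered epoch reports an amplitude near 1.  The constant is irrelevant to
every comparison downstream but is kept fixed and documented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .config import SpectralSpec


def band_magnitudes(epochs, spec: SpectralSpec, epoch_length: int = 201):
    """Single-sided FFT amplitudes at the analysed alpha bins.

    Parameters
    ----------
    epochs : (..., epoch_length) array
        Tapered analysis epochs.
    spec : SpectralSpec
    epoch_length : int
        Required trailing length (checked; the analysis geometry is 201).

    Returns
    -------
    (..., n_bins) array of amplitudes (µV), bins ``spec.band_bins`` inclusive.
    """
    epochs = np.asarray(epochs)
    if epochs.shape[-1] != epoch_length:
        raise ValueError(
            f"expected epochs of length {epoch_length}, got {epochs.shape[-1]}")
    lo, hi = spec.band_bins
    coeffs = np.fft.rfft(epochs, n=spec.nfft, axis=-1)[..., lo:hi + 1]
    return (2.0 / epoch_length) * np.abs(coeffs)


def alpha_amplitude(epochs, spec: SpectralSpec, epoch_length: int = 201):
    """Mean amplitude over the analysed alpha bins (µV)."""
    return band_magnitudes(epochs, spec, epoch_length).mean(axis=-1)


@dataclass(frozen=True)
class IAF:
    """Individual alpha frequency for one participant and region."""

    frequency: float        # Hz, one of the analysed bin frequencies
    bin_index: int
    region: str
    confident: bool         # peak/mean magnitude ratio >= 1.2


def iaf_from_magnitudes(mean_mags, spec: SpectralSpec, region: str,
                        min_peak_ratio: float = 1.2) -> IAF:
    """IAF from pre-averaged in-band magnitudes (one value per band bin)."""
    mean_mags = np.asarray(mean_mags, dtype=float)
    k = int(np.argmax(mean_mags))
    ratio = float(mean_mags[k] / mean_mags.mean()) if mean_mags.mean() > 0 else 1.0
    lo, _ = spec.band_bins
    return IAF(frequency=(lo + k) * spec.fs / spec.nfft, bin_index=lo + k,
               region=region, confident=ratio >= min_peak_ratio)


def compute_iaf(epochs, spec: SpectralSpec, region: str = "posterior",
                epoch_length: int = 201, min_peak_ratio: float = 1.2) -> IAF:
    """Pick the alpha bin with the largest average magnitude.

    ``epochs`` stacks every clean trial of every electrode in the region
    along the leading axes; magnitudes are averaged over all of them before
    the argmax, matching "average across trials then electrodes".
    """
    epochs = np.asarray(epochs)
    if epochs.size == 0:
        raise ValueError(f"no clean trials available for region {region!r}")
    mags = band_magnitudes(epochs, spec, epoch_length)
    mean_mags = mags.reshape(-1, mags.shape[-1]).mean(axis=0)
    return iaf_from_magnitudes(mean_mags, spec, region, min_peak_ratio)


# ---------------------------------------------------------------------------
# Gabor instantaneous phase
# ---------------------------------------------------------------------------

def gabor_atom(freq: float, fs: float, n_cycles_sd: float = 1.5,
               atom_len: int | None = None):
    """Complex Gabor atom: Gaussian envelope times e^{i 2 pi f t}.

    The envelope SD is ``n_cycles_sd`` cycles of ``freq``.  By default the
    atom is truncated at +-3 SD; pass ``atom_len`` (odd) to truncate harder,
    e.g. to the data length.  Normalised to unit envelope sum.
    """
    if not 0.0 < freq < fs / 2:
        raise ValueError("frequency must lie in (0, fs/2)")
    sigma = n_cycles_sd / freq * fs          # samples
    if atom_len is None:
        half = int(np.floor(3 * sigma))
    else:
        if atom_len % 2 == 0:
            raise ValueError("atom_len must be odd")
        half = (atom_len - 1) // 2
    t = np.arange(-half, half + 1)
    env = np.exp(-0.5 * (t / sigma) ** 2)
    env /= env.sum()
    return env * np.exp(2j * np.pi * freq * t / fs)


def gabor_phase(epochs, freq: float, fs: float, n_cycles_sd: float = 1.5,
                atom_len: int | None = None):
    """Instantaneous phase (radians in (-pi, pi]) at ``freq``.

    Convolution uses 'same' mode with implicit zero extension, so the
    consumer should read only samples whose neighbourhood is mostly inside
    the data (here: the pre-stimulus window of a tapered epoch).  The phase
    convention maps a cosine peak to 90 deg and a trough to 270 deg
    (i.e. arg(analytic) + pi/2, wrapped).

    The default atom is truncated to the epoch length when 3 SD would
    exceed it; an explicitly requested ``atom_len`` longer than the data is
    rejected.
    """
    epochs = np.asarray(epochs)
    if not np.issubdtype(epochs.dtype, np.floating):
        epochs = epochs.astype(float)
    n = epochs.shape[-1]
    if atom_len is not None and atom_len > n:
        raise ValueError("Gabor atom longer than the epoch")
    if atom_len is None:
        sigma = n_cycles_sd / freq * fs
        atom_len = min(2 * int(np.floor(3 * sigma)) + 1,
                       n if n % 2 == 1 else n - 1)
    cdtype = np.complex64 if epochs.dtype == np.float32 else np.complex128
    atom = gabor_atom(freq, fs, n_cycles_sd, atom_len=atom_len).astype(cdtype)
    atom = atom.reshape((1,) * (epochs.ndim - 1) + (-1,))
    analytic = fftconvolve(epochs.astype(cdtype), atom, mode="same", axes=-1)
    phase = np.angle(analytic) + np.pi / 2
    return -((-phase + np.pi) % (2 * np.pi) - np.pi)
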
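"""Frequency-domain analysis: FFT of pixel pulses and power-spectrum images.

The power-spectrum image averages the reference-normalised spectral
intensity of each pixel over a frequency band::

    P(pixel) = mean over band bins of |E_samp(f)|^2 / |E_ref(f)|^2

(the band integral implemented as a mean over bins, so a pixel whose pulse
equals the reference scores exactly 1).  Co-polarised channels (HH, VV) are
normalised with their own single-point reference trace; cross-polarised
channels (VH, HV) are conventionally displayed unnormalised, as the raw
band-mean |E_samp|^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .forward_sim import CHANNELS, EMITTER_REFERENCE, Pulse, ScanCube

log = logging.getLogger(__name__)

#: default per-channel normalisation: co-pol referenced, cross-pol raw
DEFAULT_NORMALIZE = {"HH": True, "VV": True, "VH": False, "HV": False}

#: reference-magnitude floor, relative to the in-band maximum
REFERENCE_FLOOR = 1e-6


@dataclass(frozen=True)
class BandConfig:
    """Inclusive frequency band [f1, f2] in THz."""

    f1: float
    f2: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f1 < self.f2:
            raise ValueError(f"band must satisfy 0 < f1 < f2, got [{self.f1}, {self.f2}]")


#: the published band choices: 41 bins on the Δf = 0.05 THz grid and
#: 68 bins on the Δf = 0.03 THz grid
BAND_41 = BandConfig(0.5, 2.5)
BAND_68 = BandConfig(0.505, 2.525)


@dataclass
class PowerImage:
    """A per-channel 2-D band-power image (non-negative; NaN where the
    reference magnitude underflowed)."""

    values: np.ndarray
    channel: str
    band: BandConfig
    normalized: bool


def to_spectrum(pulse: Pulse) -> tuple[np.ndarray, np.ndarray]:
    """One-sided spectrum of a pulse: (freqs_THz, complex rFFT values).

    Unitary scaling is *not* applied; Parseval holds as
    ``sum(x**2) == (|X_0|^2 + 2*sum(|X_k|^2) + |X_Nyq|^2) / N`` for even N.
    """
    return pulse.freqs_thz(), np.fft.rfft(pulse.amplitude)


def select_band(freqs_thz: np.ndarray, band: BandConfig) -> np.ndarray:
    """Indices of the grid bins with f1 <= f <= f2 (both ends inclusive)."""
    freqs = np.asarray(freqs_thz, dtype=float)
    idx = np.nonzero((freqs >= band.f1) & (freqs <= band.f2))[0]
    if idx.size == 0:
        df = float(freqs[1] - freqs[0]) if freqs.size > 1 else float("nan")
        raise ValueError(
            f"band [{band.f1}, {band.f2}] THz selects no bins on a grid with "
            f"spacing {df:.6g} THz"
        )
    return idx


def power_spectrum_image(
    cube: ScanCube,
    band: BandConfig,
    normalize: dict[str, bool] | None = None,
    weighting: str = "mean",
) -> dict[str, PowerImage]:
    """Band-power images for all four channels of a scan.

    ``normalize`` maps channel name to whether it is divided by its
    emitter's co-polarised reference spectrum (defaults: HH/VV yes, VH/HV
    no).  ``weighting`` is ``"mean"`` (band average, the default — the
    reference pixel scores exactly 1) or ``"integral"`` (Δf-weighted sum).
    Pixels whose reference magnitude underflows on any selected bin are set
    NaN and counted in the log.
    """
    if weighting not in ("mean", "integral"):
        raise ValueError(f"weighting must be 'mean' or 'integral', got {weighting!r}")
    norm = dict(DEFAULT_NORMALIZE)
    if normalize is not None:
        norm.update(normalize)
    freqs = cube.freqs_thz()
    idx = select_band(freqs, band)
    df = float(freqs[1] - freqs[0])

    out: dict[str, PowerImage] = {}
    for ch in CHANNELS:
        E = np.fft.rfft(cube.channels[ch], axis=-1)[..., idx]
        intensity = np.abs(E) ** 2
        nan_pixels = 0
        if norm[ch]:
            ref_name = EMITTER_REFERENCE[ch]
            if ref_name not in cube.references:
                raise ValueError(
                    f"channel {ch} requested normalization but reference "
                    f"{ref_name} is absent"
                )
            Eref = np.fft.rfft(cube.references[ref_name])[idx]
            mag = np.abs(Eref)
            floor = REFERENCE_FLOOR * mag.max()
            bad = mag < floor
            ratio = intensity / np.abs(Eref[None, None, :]) ** 2
            if bad.any():
                ratio[..., bad] = np.nan
            intensity = ratio
        if weighting == "mean":
            values = np.nanmean(intensity, axis=-1) if norm[ch] else intensity.mean(axis=-1)
            if norm[ch] and np.isnan(intensity).all(axis=-1).any():
                values = np.where(np.isnan(intensity).all(axis=-1), np.nan, values)
        else:
            values = intensity.sum(axis=-1) * df
        nan_pixels = int(np.isnan(values).sum())
        if nan_pixels:
            log.warning("channel %s: %d pixel(s) NaN from reference underflow",
                        ch, nan_pixels)
        out[ch] = PowerImage(values=values, channel=ch, band=band,
                             normalized=bool(norm[ch]))
    return out


def power_images_from_field(Sfield: np.ndarray) -> dict[str, np.ndarray]:
    """Per-frequency power images straight from a deconvolved scattering field.

    Returns channel -> ``(rows, cols, n_freq)`` arrays of squared field
    magnitudes.  These are, bin for bin, the normalised power images of the
    corresponding channels, and they are computed with the exact same
    floating-point expression the Mueller elements M11/M22/M12/M21 use, so
    the two routes agree bit-for-bit.
    """
    Sfield = np.asarray(Sfield)
    return {
        "VV": np.abs(Sfield[..., 0, 0]) ** 2,
        "VH": np.abs(Sfield[..., 0, 1]) ** 2,
        "HV": np.abs(Sfield[..., 1, 0]) ** 2,
        "HH": np.abs(Sfield[..., 1, 1]) ** 2,
    }
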
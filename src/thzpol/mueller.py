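"""Mueller-matrix imaging from four-channel polarimetric scans.

Each pixel's four complex channel spectra form a 2×2 scattering matrix
S = [[Svv, Svh], [Shv, Shh]] per frequency.  The 16-element Mueller matrix
is built from S in the radar-style linear-polarisation form::

    M = [ |Svv|^2        |Svh|^2        Re(Svh* Svv)        -Im(Svh* Svv)
          |Shv|^2        |Shh|^2        Re(Shv Shh*)        -Im(Shv Shh*)
          2 Re(Svv Shv*) 2 Re(Svh Shh*) Re(Svv Shh*+Svh Shv*) -Im(Svv Shh*-Svh Shv*)
          2 Im(Svv Shv*) 2 Im(Svh Shh*) Im(Svv Shh*+Svh Shv*)  Re(Svv Shh*-Svh Shv*) ]

so M11, M22, M12, M21 are the per-frequency power images of the VV, HH,
VH, HV channels.  Because every element is a bilinear form of one rank-one
field, five algebraic identities hold exactly at each frequency
(e.g. M13² + M14² = M11·M12); band averaging relaxes them to Cauchy–Schwarz
inequalities.  These identities are the internal consistency oracle of the
whole pipeline.

Deconvolution schemes (how raw channel spectra become S entries):

- ``"emitter"`` (default): each channel is divided by the single-point
  reference of its *emitter's* co-polarised channel (VV, HV by ref VV;
  HH, VH by ref HH) — the emitter spectrum is the common factor of both
  detector arms.
- ``"detector"``: divided by the reference matching the detector arm.
- ``"raw"``: no reference division (the display convention for cross-pol
  power images).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .forward_sim import ScanCube
from .spectra import REFERENCE_FLOOR, BandConfig, select_band

log = logging.getLogger(__name__)

_SCHEME_REFS = {
    "emitter": {"VV": "VV", "HV": "VV", "HH": "HH", "VH": "HH"},
    "detector": {"VV": "VV", "HV": "HH", "HH": "HH", "VH": "VV"},
    "raw": None,
}


@dataclass
class ScatteringField:
    """Per-pixel, per-frequency scattering matrices recovered from a scan."""

    freqs_thz: np.ndarray
    S: np.ndarray  # (rows, cols, n_freq, 2, 2) complex
    scheme: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.S.shape[:2]


@dataclass
class MuellerStack:
    """Mueller elements per pixel: ``(rows, cols, n_freq, 4, 4)`` for a
    per-frequency stack or ``(rows, cols, 4, 4)`` after band averaging."""

    M: np.ndarray
    freqs_thz: np.ndarray | None
    band: BandConfig | None
    scheme: str

    @property
    def band_averaged(self) -> bool:
        return self.M.ndim == 4


def scattering_from_scan(
    cube: ScanCube, scheme: str = "emitter", band: BandConfig | None = None
) -> ScatteringField:
    """Recover the per-pixel scattering field from a measured scan.

    ``band`` optionally restricts the output to the selected bins (saving
    memory); otherwise the full rFFT grid is returned.  Bins where the
    required reference magnitude underflows are set NaN and logged.
    """
    if scheme not in _SCHEME_REFS:
        raise ValueError(
            f"unknown deconvolution scheme {scheme!r}; "
            f"expected one of {sorted(_SCHEME_REFS)}"
        )
    freqs = cube.freqs_thz()
    idx = select_band(freqs, band) if band is not None else np.arange(freqs.size)

    refs = _SCHEME_REFS[scheme]
    ref_spec: dict[str, np.ndarray] = {}
    if refs is not None:
        for ch, ref_name in refs.items():
            if ref_name not in cube.references:
                raise ValueError(
                    f"scheme {scheme!r} needs reference {ref_name} for channel "
                    f"{ch}, but it is absent from the cube"
                )
        for name in set(refs.values()):
            E = np.fft.rfft(cube.references[name])[idx]
            mag = np.abs(E)
            floor = REFERENCE_FLOOR * mag.max()
            bad = mag < floor
            if bad.any():
                log.warning("reference %s: %d bin(s) below magnitude floor",
                            name, int(bad.sum()))
                E = E.astype(complex).copy()
                E[bad] = np.nan
            ref_spec[name] = E

    rows, cols = cube.shape
    S = np.empty((rows, cols, idx.size, 2, 2), dtype=complex)
    pos = {"VV": (0, 0), "VH": (0, 1), "HV": (1, 0), "HH": (1, 1)}
    for ch, (i, j) in pos.items():
        E = np.fft.rfft(cube.channels[ch], axis=-1)[..., idx]
        if refs is not None:
            E = E / ref_spec[refs[ch]][None, None, :]
        S[..., i, j] = E
    return ScatteringField(freqs_thz=freqs[idx], S=S, scheme=scheme)


def mueller_from_S(S: np.ndarray) -> np.ndarray:
    """Element-wise evaluation of the 16-element Mueller matrix.

    ``S`` is any stack ``(..., 2, 2)``; returns ``(..., 4, 4)`` real.  No
    normalisation is applied.
    """
    S = np.asarray(S, dtype=complex)
    Svv, Svh = S[..., 0, 0], S[..., 0, 1]
    Shv, Shh = S[..., 1, 0], S[..., 1, 1]
    M = np.empty(S.shape[:-2] + (4, 4), dtype=float)
    a = np.conj(Svh) * Svv
    b = Shv * np.conj(Shh)
    c = Svv * np.conj(Shv)
    d = Svh * np.conj(Shh)
    e = Svv * np.conj(Shh) + Svh * np.conj(Shv)
    g = Svv * np.conj(Shh) - Svh * np.conj(Shv)
    M[..., 0, 0] = np.abs(Svv) ** 2
    M[..., 0, 1] = np.abs(Svh) ** 2
    M[..., 0, 2] = a.real
    M[..., 0, 3] = -a.imag
    M[..., 1, 0] = np.abs(Shv) ** 2
    M[..., 1, 1] = np.abs(Shh) ** 2
    M[..., 1, 2] = b.real
    M[..., 1, 3] = -b.imag
    M[..., 2, 0] = 2.0 * c.real
    M[..., 2, 1] = 2.0 * d.real
    M[..., 2, 2] = e.real
    M[..., 2, 3] = -g.imag
    M[..., 3, 0] = 2.0 * c.imag
    M[..., 3, 1] = 2.0 * d.imag
    M[..., 3, 2] = e.imag
    M[..., 3, 3] = g.real
    return M


def mueller_stack(field: ScatteringField) -> MuellerStack:
    """Per-frequency Mueller stack of a recovered scattering field."""
    return MuellerStack(M=mueller_from_S(field.S), freqs_thz=field.freqs_thz,
                        band=None, scheme=field.scheme)


def band_average_mueller(stack: MuellerStack, band: BandConfig) -> MuellerStack:
    """Element-wise mean of a per-frequency stack over the band bins."""
    if stack.band_averaged:
        raise ValueError("stack is already band-averaged")
    idx = select_band(stack.freqs_thz, band)
    M = stack.M[..., idx, :, :].mean(axis=-3)
    return MuellerStack(M=M, freqs_thz=None, band=band, scheme=stack.scheme)


def rank_one_residuals(M: np.ndarray) -> np.ndarray:
    """Relative residuals of the five exact per-frequency identities.

    For Mueller matrices built from a single scattering matrix these vanish;
    they are the independent algebraic oracle for :func:`mueller_from_S`.
    Returns an array ``(..., 5)`` of |lhs − rhs| / max(|lhs|, |rhs|, 1e-300).
    """
    M = np.asarray(M, dtype=float)
    lhs = np.stack([
        M[..., 0, 2] ** 2 + M[..., 0, 3] ** 2,
        M[..., 1, 2] ** 2 + M[..., 1, 3] ** 2,
        M[..., 2, 0] ** 2 + M[..., 3, 0] ** 2,
        M[..., 2, 1] ** 2 + M[..., 3, 1] ** 2,
        M[..., 2, 2] ** 2 + M[..., 2, 3] ** 2 + M[..., 3, 2] ** 2 + M[..., 3, 3] ** 2,
    ], axis=-1)
    rhs = np.stack([
        M[..., 0, 0] * M[..., 0, 1],
        M[..., 1, 0] * M[..., 1, 1],
        4.0 * M[..., 0, 0] * M[..., 1, 0],
        4.0 * M[..., 0, 1] * M[..., 1, 1],
        2.0 * (M[..., 0, 0] * M[..., 1, 1] + M[..., 0, 1] * M[..., 1, 0]),
    ], axis=-1)
    scale = np.maximum(np.maximum(np.abs(lhs), np.abs(rhs)), 1e-300)
    return np.abs(lhs - rhs) / scale


def stokes_from_field(Ev: complex, Eh: complex) -> np.ndarray:
    """Stokes vector (s0, s1, s2, s3) of a fully polarised field.

    Linear-basis definition with s3 = −2 Im(Ev Eh*): a right-circular state
    (Eh leading Ev by 90°, i.e. Ev = 1/√2, Eh = i/√2) has s3 = +1.
    Satisfies s0² = s1² + s2² + s3² exactly for any (Ev, Eh).
    """
    Ev = np.asarray(Ev, dtype=complex)
    Eh = np.asarray(Eh, dtype=complex)
    s0 = np.abs(Ev) ** 2 + np.abs(Eh) ** 2
    s1 = np.abs(Ev) ** 2 - np.abs(Eh) ** 2
    cross = Ev * np.conj(Eh)
    s2 = 2.0 * cross.real
    s3 = -2.0 * cross.imag
    return np.stack([s0, s1, s2, s3], axis=-1)
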
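"""Per-pixel complex scattering matrices for oblique reflection.

The sample is modelled as a planar interface probed at 30 degrees from the
surface normal.  The horizontal (H) channel is s-polarised (field
perpendicular to the plane of incidence) and the vertical (V) channel is
p-polarised.  Scattering matrices are expressed in the (V, H) basis::

    S = [[Svv, Svh],
         [Shv, Shh]]

with Sxy the complex field amplitude detected in polarisation x for
emission in polarisation y.

Isotropic pixels reflect with the Fresnel amplitudes, Svv = rp, Shh = rs,
and cannot mix the channels.  Fibrous (collagen) pixels additionally act as
a linear retarder whose fast axis lies along the in-plane fibre
orientation: the beam traverses the birefringent layer, reflects, and
traverses it again, so the interface response is sandwiched between two
single-pass retarder Jones matrices.  That symmetric composition makes the
matrix reciprocal (Svh = Shv) by construction.

Fresnel sign convention (Hecht): rs = (n1 cosθi − n2 cosθt)/(n1 cosθi +
n2 cosθt), rp = (n2 cosθi − n1 cosθt)/(n2 cosθi + n1 cosθt); at normal
incidence rs = −rp = (n1 − n2)/(n1 + n2).  Downstream images depend only on
magnitudes and relative phases.

Imperfect wire-grid polarisers leak a fraction ε of the orthogonal field on
both the emitter and the detector side, modelled as L(ε)·S·L(ε) with
L = [[1, ε], [ε, 1]].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import FIBROUS_CLASSES, LabelMap, OpticalProperties, TissueClass

#: Speed of light in micrometres per picosecond (path lengths are in µm,
#: frequencies in THz = 1/ps).
C_UM_PER_PS = 299.792458


@dataclass(frozen=True)
class IncidenceGeometry:
    """Angle of incidence (from the surface normal) and incidence medium."""

    theta_deg: float = 30.0
    n_incident: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_deg < 90.0:
            raise ValueError(f"theta_deg must be in [0, 90), got {self.theta_deg}")
        if self.n_incident < 1.0:
            raise ValueError(f"n_incident must be >= 1, got {self.n_incident}")


def fresnel_rs_rp(n1: float, n2: complex, theta_deg: float):
    """Amplitude reflection coefficients (rs, rp) at a planar interface.

    ``n1`` is the real index of the incidence medium, ``n2`` the (possibly
    complex, absorbing) index of the sample, ``theta_deg`` the angle of
    incidence.  ``n2`` may be an array; the result broadcasts.
    """
    n1 = float(n1)
    if n1 < 1.0:
        raise ValueError(f"n1 must be >= 1, got {n1}")
    n2 = np.asarray(n2, dtype=complex)
    if np.any(n2.imag < 0):
        raise ValueError("extinction coefficient (Im n2) must be >= 0")
    theta = np.deg2rad(theta_deg)
    cos_i = np.cos(theta)
    sin_t = n1 * np.sin(theta) / n2
    cos_t = np.sqrt(1.0 - sin_t**2)  # principal branch; Im(n2) >= 0 keeps it physical
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n2 * cos_i - n1 * cos_t) / (n2 * cos_i + n1 * cos_t)
    return rs, rp


def retardance(frequency_thz, delta_n: float, layer_thickness_um: float):
    """Double-pass retardance δ = 2π f Δn (2d) / c of the fibrous layer."""
    f = np.asarray(frequency_thz, dtype=float)
    return 2.0 * np.pi * f * delta_n * (2.0 * layer_thickness_um) / C_UM_PER_PS


def _retarder_vh(delta, axis_deg: float) -> np.ndarray:
    """Jones matrix of a linear retarder in the (V, H) basis.

    ``delta`` is the retardance (may be an array over frequency); the fast
    axis lies at ``axis_deg`` CCW from the H (+x) axis.  Returns an array of
    shape ``delta.shape + (2, 2)``.
    """
    delta = np.asarray(delta, dtype=float)
    th = np.deg2rad(axis_deg)
    c2, s2 = np.cos(2 * th), np.sin(2 * th)
    a = np.cos(delta / 2.0)
    b = 1j * np.sin(delta / 2.0)
    # In (H, V): R(-th) diag(e^{i d/2}, e^{-i d/2}) R(th)
    #          = cos(d/2) I + i sin(d/2) [[c2, s2], [s2, -c2]]
    # Reordering to (V, H) swaps both indices (flips the sign of c2).
    out = np.empty(delta.shape + (2, 2), dtype=complex)
    out[..., 0, 0] = a - b * c2
    out[..., 0, 1] = b * s2
    out[..., 1, 0] = b * s2
    out[..., 1, 1] = a + b * c2
    return out


def pixel_scattering(
    props: OpticalProperties,
    optic_axis_deg: float | None,
    geometry: IncidenceGeometry,
    frequency_thz,
) -> np.ndarray:
    """Scattering matrix of one pixel, sampled at ``frequency_thz``.

    Returns an array of shape ``freq.shape + (2, 2)`` in the (V, H) basis.
    Isotropic pixels give diag(rp, rs); birefringent pixels compose that
    interface response with a single-pass retarder on the way in and out
    (retardance δ/2 per pass, δ the double-pass value), which preserves
    reciprocity Svh = Shv exactly.
    """
    f = np.asarray(frequency_thz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    rs, rp = fresnel_rs_rp(geometry.n_incident, props.n_complex, geometry.theta_deg)
    S = np.zeros(f.shape + (2, 2), dtype=complex)
    S[..., 0, 0] = rp
    S[..., 1, 1] = rs
    if props.delta_n > 0.0:
        if optic_axis_deg is None or not np.isfinite(optic_axis_deg):
            raise ValueError("fibrous pixel requires a defined optic_axis_deg")
        delta = retardance(f, props.delta_n, props.layer_thickness_um)
        P = _retarder_vh(delta / 2.0, optic_axis_deg)  # single pass
        S = P @ S @ P
    return S


def apply_polarizer_leakage(S: np.ndarray, epsilon: float) -> np.ndarray:
    """Sandwich S between emitter- and detector-side leakage matrices.

    ``S`` may be a single 2×2 matrix or any stack ``(..., 2, 2)``.  ε = 0 is
    the identity; ε must satisfy 0 ≤ ε < 1.
    """
    if not 0.0 <= epsilon < 1.0:
        raise ValueError(f"leakage epsilon must be in [0, 1), got {epsilon}")
    S = np.asarray(S, dtype=complex)
    if epsilon == 0.0:
        return S.copy()
    L = np.array([[1.0, epsilon], [epsilon, 1.0]])
    return L @ S @ L


def scattering_field(
    labels: LabelMap,
    optics: dict[TissueClass, OpticalProperties],
    geometry: IncidenceGeometry,
    freqs_thz: np.ndarray,
    epsilon_leakage: float = 0.0,
) -> np.ndarray:
    """Scattering matrices for a whole label map.

    Returns ``(rows, cols, n_freq, 2, 2)`` complex.  Pixels sharing a class
    and (for fibrous classes) an optic-axis angle are computed once — the
    phantom paints piecewise-constant regions, so this is the dominant
    fast path.
    """
    rows, cols = labels.shape
    f = np.asarray(freqs_thz, dtype=float)
    out = np.empty((rows, cols, f.size, 2, 2), dtype=complex)
    classes = labels.classes
    axis = labels.optic_axis_deg
    for code in np.unique(classes):
        cls = TissueClass(int(code))
        if cls not in optics:
            raise ValueError(f"no optical properties provided for class {cls.name}")
        props = optics[cls]
        sel = classes == code
        if cls in FIBROUS_CLASSES and props.delta_n > 0.0:
            for ax in np.unique(axis[sel]):
                if not np.isfinite(ax):
                    raise ValueError(f"fibrous class {cls.name} has undefined optic axis")
                sub = sel & (axis == ax)
                out[sub] = pixel_scattering(props, float(ax), geometry, f)
        else:
            out[sel] = pixel_scattering(props, None, geometry, f)
    if epsilon_leakage:
        out = apply_polarizer_leakage(out, epsilon_leakage)
    return out
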
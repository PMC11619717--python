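"""Sample-rotation cross-polarization analysis.

A fibrous specimen rotated on the scanning window modulates the
cross-polarised band power as sin²(2(θ0 + φ)) — zero when the fibre axis
lies along either polariser axis, maximal at 45° to them, with 90°
periodicity.  Sweeping the rotation angle φ and fitting that law to the
measured cross-pol power recovers the in-plane fibre orientation θ0
(mod 90°) without ever resolving individual fibres.

Cross-pol powers are the *unnormalised* band means on a common scale
across angles, so the sweep is directly comparable angle to angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import forward_sim, spectra
from .optics import IncidenceGeometry
from .phantom import LabelMap, OpticalProperties, TissueClass, rotate_label_map

#: the co-polarised partner observed alongside each cross channel
COPOL_PARTNER = {"VH": "HH", "HV": "VV"}

#: default mask: every tissue class, excluding embedding/background media
DEFAULT_MASK_CLASSES = frozenset({
    TissueClass.CANCER, TissueClass.FAT, TissueClass.COLLAGEN,
    TissueClass.MINERALIZATION,
})


@dataclass
class RotationSeries:
    """Cross- and co-polarised band power versus sample rotation angle."""

    angles_deg: np.ndarray
    crosspol_power: np.ndarray
    copol_power: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        if not (len(self.angles_deg) == len(self.crosspol_power) == len(self.copol_power)):
            raise ValueError("angle and power lists must have equal length")


@dataclass
class OrientationFit:
    """Least-squares fit of a + b·sin²(2(θ0 + φ)) to a rotation series."""

    theta0_deg: float | None
    offset: float
    amplitude: float
    residual_rms: float
    isotropic: bool


def rotation_sweep(
    labels: LabelMap,
    optics_map: dict[TissueClass, OpticalProperties],
    geometry: IncidenceGeometry,
    config: forward_sim.AcquisitionConfig,
    angles_deg,
    channel: str = "VH",
    band: spectra.BandConfig = spectra.BAND_68,
    mask_classes=None,
    medium: str = "block",
) -> RotationSeries:
    """Rescan the phantom at each rotation angle and record band powers.

    One simulated scan and one set of power images per angle; powers are
    means over the mask (default: all tissue classes), which is rotated
    with the phantom so the pixel population stays comparable.  The seed of
    each angle's scan is derived deterministically from ``config.seed``.
    """
    if channel not in COPOL_PARTNER:
        raise ValueError(f"cross channel must be VH or HV, got {channel!r}")
    angles = np.asarray(list(angles_deg), dtype=float)
    if np.any((angles < 0) | (angles >= 360)):
        raise ValueError("rotation angles must lie in [0, 360)")
    if mask_classes is None:
        mask_classes = DEFAULT_MASK_CLASSES
    copol = COPOL_PARTNER[channel]

    cross_p = np.empty(angles.size)
    co_p = np.empty(angles.size)
    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(angles.size)]
    from dataclasses import replace as _replace

    for k, phi in enumerate(angles):
        cfg = _replace(config, seed=child_seeds[k])
        cube = forward_sim.simulate_scan(
            labels, optics_map, geometry, cfg, rotation_deg=float(phi), medium=medium
        )
        rotated = rotate_label_map(labels, float(phi)) if phi else labels
        mask = rotated.mask(mask_classes)
        if not mask.any():
            raise ValueError(f"mask empty after rotating to {phi} deg")
        images = spectra.power_spectrum_image(cube, band)
        cross_p[k] = float(np.nanmean(images[channel].values[mask]))
        co_p[k] = float(np.nanmean(images[copol].values[mask]))
    return RotationSeries(angles_deg=angles, crosspol_power=cross_p,
                          copol_power=co_p, channel=channel)


def estimate_axis_orientation(
    series: RotationSeries, min_modulation: float = 0.05
) -> OrientationFit:
    """Recover the fibre orientation θ0 (mod 90°) from a rotation series.

    Fits ``P(φ) = a + b·sin²(2(θ0 + φ))`` by exact linear least squares in
    the equivalent basis ``A + B·cos(4φ) + C·sin(4φ)``.  If the modulation
    amplitude b is below ``min_modulation`` of the mean level the series is
    declared isotropic and no orientation is reported.
    """
    phi = np.deg2rad(np.asarray(series.angles_deg, dtype=float))
    if np.unique(np.round(phi, 12)).size < 4:
        raise ValueError("need at least 4 distinct rotation angles")
    y = np.asarray(series.crosspol_power, dtype=float)
    X = np.column_stack([np.ones_like(phi), np.cos(4 * phi), np.sin(4 * phi)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    A, B, C = coef
    resid = y - X @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    b = 2.0 * float(np.hypot(B, C))
    a = float(A - b / 2.0)
    mean_level = max(float(np.mean(np.abs(y))), 1e-300)
    if b < min_modulation * mean_level:
        return OrientationFit(theta0_deg=None, offset=a, amplitude=b,
                              residual_rms=rms, isotropic=True)
    # a + b sin^2(2(t0+phi)) = (a + b/2) - (b/2) cos(4 t0) cos(4 phi)
    #                                    + (b/2) sin(4 t0) sin(4 phi)
    theta0 = np.rad2deg(np.arctan2(C, -B) / 4.0) % 90.0
    return OrientationFit(theta0_deg=float(theta0), offset=a, amplitude=b,
                          residual_rms=rms, isotropic=False)
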
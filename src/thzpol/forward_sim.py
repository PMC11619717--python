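"""Forward synthesis of raster-scanned polarimetric THz pulse cubes.

Emulates a reflection-mode time-domain scanner: every pixel of a phantom is
probed with a broadband picosecond pulse in four polarisation channels
(HH, VH, VV, HV — first letter detector, second emitter), and a single
reference trace per co-polarised channel is recorded at a no-tissue point
(the paraffin surface for block specimens, the bare slide for fresh ones).

The synthesis is the exact inverse of the analysis chain: the reference
pulse spectrum is multiplied by the pixel's scattering-matrix entry and
transformed back to the time domain.  Optional additive white Gaussian
noise is drawn independently per pulse and per averaging repeat; block
scans average five pulses per pixel, which is what suppresses the weak
cross-polarised channels enough to image them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import optics as _optics
from .phantom import LabelMap, OpticalProperties, TissueClass, rotate_label_map

#: channel name -> (row, col) index into the (V, H)-basis scattering matrix
CHANNELS = ("HH", "VH", "VV", "HV")
_CHANNEL_INDEX = {"VV": (0, 0), "VH": (0, 1), "HV": (1, 0), "HH": (1, 1)}
#: emitter polarisation of each channel (second letter)
EMITTER = {"HH": "H", "VH": "H", "VV": "V", "HV": "V"}
#: co-polarised reference channel matching each channel's *emitter*
EMITTER_REFERENCE = {"HH": "HH", "VH": "HH", "VV": "VV", "HV": "VV"}

REFERENCE_CLASS = {"block": TissueClass.PARAFFIN, "fresh": TissueClass.SLIDE_BACKGROUND}


@dataclass(frozen=True)
class Pulse:
    """A uniformly sampled time-domain trace (picoseconds, arbitrary units)."""

    t_ps: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        if self.t_ps.ndim != 1 or self.t_ps.shape != self.amplitude.shape:
            raise ValueError("time axis and amplitude must be matching 1-D arrays")
        dt = np.diff(self.t_ps)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            raise ValueError("time axis must be uniform")

    @property
    def dt_ps(self) -> float:
        return float(self.t_ps[1] - self.t_ps[0])

    @property
    def n_samples(self) -> int:
        return self.t_ps.size

    def freqs_thz(self) -> np.ndarray:
        return np.fft.rfftfreq(self.n_samples, self.dt_ps)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Everything the virtual scanner needs besides the phantom.

    The 1024-sample window sets the frequency grid: Δf = 1/window.  Two
    presets pin the grid to the published band bookkeeping — a 20 ps window
    (Δf = 0.05 THz; the 0.5–2.5 THz band then holds exactly 41 bins) and a
    33.33 ps window (Δf = 0.03 THz; 0.505–2.525 THz holds exactly 68 bins).
    """

    n_samples: int = 1024
    window_ps: float = 35.0
    pulse_center_ps: float = 8.0
    pulse_width_ps: float = 0.1
    noise_sigma: float = 0.0
    n_average: int = 1
    epsilon_leakage: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.window_ps <= 0 or self.pulse_width_ps <= 0:
            raise ValueError("window_ps and pulse_width_ps must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_average < 1:
            raise ValueError("n_average must be >= 1")
        if not 0.0 <= self.epsilon_leakage < 1.0:
            raise ValueError("epsilon_leakage must be in [0, 1)")

    @property
    def dt_ps(self) -> float:
        return self.window_ps / self.n_samples

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ps

    def freqs_thz(self) -> np.ndarray:
        return np.fft.rfftfreq(self.n_samples, self.dt_ps)

    @classmethod
    def grid_41(cls, **kw) -> "AcquisitionConfig":
        """Δf = 0.05 THz preset (41 bins across 0.5–2.5 THz), 5-pulse averaging
        as in block-specimen scans."""
        kw.setdefault("n_average", 5)
        return cls(window_ps=20.0, **kw)

    @classmethod
    def grid_68(cls, **kw) -> "AcquisitionConfig":
        """Δf = 0.03 THz preset (68 bins across 0.505–2.525 THz)."""
        return cls(window_ps=100.0 / 3.0, **kw)


@dataclass(frozen=True)
class ScanMeta:
    step_um: float = 150.0
    theta_deg: float = 30.0
    rotation_deg: float = 0.0
    n_average: int = 1
    medium: str = "block"
    seed: int = 0
    pixel_order: str = "row-major-flyback"


@dataclass
class ScanCube:
    """Four-channel raster of time-domain pulses plus reference traces."""

    channels: dict[str, np.ndarray]  # name -> (rows, cols, n_samples)
    references: dict[str, np.ndarray]  # name -> (n_samples,)
    t_ps: np.ndarray
    meta: ScanMeta

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"scan cube is missing channel(s): {', '.join(missing)}")
        shapes = {c: self.channels[c].shape for c in CHANNELS}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        shape = shapes["HH"]
        if len(shape) != 3 or shape[2] != self.t_ps.size:
            raise ValueError(
                f"channel arrays must be (rows, cols, {self.t_ps.size}), got {shape}"
            )
        for name, ref in self.references.items():
            if ref.shape != (self.t_ps.size,):
                raise ValueError(f"reference {name} length {ref.shape} != time axis")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels["HH"].shape[:2]

    @property
    def n_samples(self) -> int:
        return self.t_ps.size

    def freqs_thz(self) -> np.ndarray:
        dt = float(self.t_ps[1] - self.t_ps[0])
        return np.fft.rfftfreq(self.n_samples, dt)


def reference_pulse(config: AcquisitionConfig) -> Pulse:
    """The emitter pulse: a Gaussian first derivative, peak amplitude 1.

    Its magnitude spectrum must stay above 1 % of its peak across
    0.1–4 THz (the usable instrument band); a width that violates that
    raises an error quoting the band the pulse actually supports.
    """
    t = config.time_axis()
    s = config.pulse_width_ps
    x = (t - config.pulse_center_ps) / s
    amp = -x * np.exp(-0.5 * x**2) * np.exp(0.5)  # peak |amplitude| = 1
    pulse = Pulse(t_ps=t, amplitude=amp)
    spec = np.abs(np.fft.rfft(amp))
    freqs = config.freqs_thz()
    floor = 0.01 * spec.max()
    usable = freqs[spec >= floor]
    lo, hi = (usable.min(), usable.max()) if usable.size else (np.nan, np.nan)
    band_lo, band_hi = 0.1, 4.0
    inside = (freqs >= band_lo) & (freqs <= band_hi)
    if not np.all(spec[inside] >= floor):
        raise ValueError(
            f"pulse width {s} ps does not cover {band_lo}-{band_hi} THz; "
            f"usable band is {lo:.3f}-{hi:.3f} THz"
        )
    return pulse


def synthesize_pixel(
    S_of_f: np.ndarray,
    ref: Pulse,
    config: AcquisitionConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Time-domain pulses of one pixel from its per-frequency scattering matrix.

    ``S_of_f`` must be sampled on the rFFT grid of ``ref`` — shape
    ``(n_freq, 2, 2)`` with ``n_freq = n_samples//2 + 1``.  Each channel is
    the inverse FFT of (reference spectrum × matrix entry), then averaged
    over ``n_average`` independent additive-noise realisations.
    """
    S_of_f = np.asarray(S_of_f, dtype=complex)
    n_freq = ref.n_samples // 2 + 1
    if S_of_f.shape != (n_freq, 2, 2):
        raise ValueError(
            f"S must be sampled on the rFFT grid of the reference: expected "
            f"({n_freq}, 2, 2), got {S_of_f.shape}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    E0 = np.fft.rfft(ref.amplitude)
    out: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        i, j = _CHANNEL_INDEX[ch]
        clean = np.fft.irfft(E0 * S_of_f[:, i, j], n=ref.n_samples)
        if config.noise_sigma > 0:
            acc = np.zeros_like(clean)
            for _ in range(config.n_average):
                acc += clean + rng.normal(0.0, config.noise_sigma, clean.shape)
            out[ch] = acc / config.n_average
        else:
            out[ch] = clean
    return out


def _reference_traces(
    optics_map: dict[TissueClass, OpticalProperties],
    geometry: _optics.IncidenceGeometry,
    config: AcquisitionConfig,
    medium: str,
    E0: np.ndarray,
    freqs: np.ndarray,
) -> dict[str, np.ndarray]:
    """Co-polarised reference traces reflected off the no-tissue class.

    Synthesised through the exact same code path as sample pixels (a 1×1
    label map of the reference class), so a sample pixel of the reference
    class normalises to exactly 1.
    """
    ref_class = REFERENCE_CLASS[medium]
    point = LabelMap(
        classes=np.full((1, 1), int(ref_class), dtype=np.uint8),
        optic_axis_deg=np.full((1, 1), np.nan),
        step_um=1.0,
    )
    S = _optics.scattering_field(
        point, optics_map, geometry, freqs, epsilon_leakage=config.epsilon_leakage
    )
    n = 2 * (freqs.size - 1)
    return {
        "VV": np.fft.irfft(E0[None, None, :] * S[..., 0, 0], n=n, axis=-1)[0, 0],
        "HH": np.fft.irfft(E0[None, None, :] * S[..., 1, 1], n=n, axis=-1)[0, 0],
    }


def simulate_scan(
    labels: LabelMap,
    optics_map: dict[TissueClass, OpticalProperties],
    geometry: _optics.IncidenceGeometry,
    config: AcquisitionConfig,
    rotation_deg: float = 0.0,
    medium: str = "block",
) -> ScanCube:
    """Simulate a full raster scan of a phantom.

    ``rotation_deg`` rotates the specimen on the scanning window: the label
    map is resampled (nearest neighbour) about its centre and the rotation
    is added to every fibre optic axis.  References are synthesised from
    the medium's no-tissue class.  Deterministic given ``config.seed``.
    """
    if medium not in REFERENCE_CLASS:
        raise ValueError(f"unknown medium {medium!r}; expected 'fresh' or 'block'")
    rows, cols = labels.shape
    if rows == 0 or cols == 0:
        raise ValueError("empty phantom: label map has no pixels")
    if rotation_deg:
        labels = rotate_label_map(labels, rotation_deg)

    ref = reference_pulse(config)
    freqs = config.freqs_thz()
    E0 = np.fft.rfft(ref.amplitude)

    Sfield = _optics.scattering_field(
        labels, optics_map, geometry, freqs, epsilon_leakage=config.epsilon_leakage
    )  # (rows, cols, nf, 2, 2)

    rng = np.random.default_rng(config.seed)
    channels: dict[str, np.ndarray] = {}
    n = config.n_samples
    for ch in CHANNELS:
        i, j = _CHANNEL_INDEX[ch]
        spec = E0[None, None, :] * Sfield[..., i, j]
        clean = np.fft.irfft(spec, n=n, axis=-1)
        if config.noise_sigma > 0:
            acc = np.zeros_like(clean)
            for _ in range(config.n_average):
                acc += clean + rng.normal(0.0, config.noise_sigma, clean.shape)
            channels[ch] = acc / config.n_average
        else:
            channels[ch] = clean

    references = _reference_traces(optics_map, geometry, config, medium, E0, freqs)
    meta = ScanMeta(
        step_um=labels.step_um,
        theta_deg=geometry.theta_deg,
        rotation_deg=rotation_deg,
        n_average=config.n_average,
        medium=medium,
        seed=config.seed,
    )
    return ScanCube(channels=channels, references=references, t_ps=ref.t_ps, meta=meta)


def cube_from_scattering(
    Sfield: np.ndarray,
    config: AcquisitionConfig,
    meta: ScanMeta | None = None,
) -> ScanCube:
    """Build a ScanCube directly from a known per-pixel scattering field.

    ``Sfield`` has shape ``(rows, cols, n_freq, 2, 2)`` on the rFFT grid of
    the configured pulse.  References are the bare emitter pulse (identity
    reflection), so the analysis chain recovers ``Sfield`` itself — the
    controlled setting for forward–inverse round-trip checks.
    """
    Sfield = np.asarray(Sfield, dtype=complex)
    ref = reference_pulse(config)
    n_freq = config.n_samples // 2 + 1
    if Sfield.ndim != 5 or Sfield.shape[2:] != (n_freq, 2, 2):
        raise ValueError(
            f"Sfield must be (rows, cols, {n_freq}, 2, 2); got {Sfield.shape}"
        )
    E0 = np.fft.rfft(ref.amplitude)
    rng = np.random.default_rng(config.seed)
    channels: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        i, j = _CHANNEL_INDEX[ch]
        clean = np.fft.irfft(E0[None, None, :] * Sfield[..., i, j],
                             n=config.n_samples, axis=-1)
        if config.noise_sigma > 0:
            acc = np.zeros_like(clean)
            for _ in range(config.n_average):
                acc += clean + rng.normal(0.0, config.noise_sigma, clean.shape)
            channels[ch] = acc / config.n_average
        else:
            channels[ch] = clean
    references = {"VV": ref.amplitude.copy(), "HH": ref.amplitude.copy()}
    if meta is None:
        meta = ScanMeta(n_average=config.n_average, seed=config.seed)
    return ScanCube(channels=channels, references=references, t_ps=ref.t_ps, meta=meta)


def mirror_scan(
    config: AcquisitionConfig,
    rows: int = 4,
    cols: int = 4,
) -> ScanCube:
    """Scan of the gold calibration mirror.

    The mirror is the instrument's identity target: every pixel responds
    with the identity channel matrix, so with perfect polarisers the
    cross-polarised channels are identically zero, and with leakage ε the
    sandwich L·I·L = [[1+ε², 2ε], [2ε, 1+ε²]] puts a cross/co amplitude
    ratio of 2ε/(1+ε²) in every pixel — the small-but-nonzero mirror
    cross-pol seen in practice.
    """
    n_freq = config.n_samples // 2 + 1
    S = np.zeros((rows, cols, n_freq, 2, 2), dtype=complex)
    S[..., 0, 0] = 1.0
    S[..., 1, 1] = 1.0
    S = _optics.apply_polarizer_leakage(S, config.epsilon_leakage)
    meta = ScanMeta(medium="block", n_average=config.n_average, seed=config.seed)
    return cube_from_scattering(S, config, meta=meta)
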
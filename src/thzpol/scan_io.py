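"""HDF5 container for scan cubes and helpers for derived products.

Schema::

    /channels/{HH,VH,VV,HV}   float64 (rows, cols, n_samples)
    /references/{HH,VV,...}   float64 (n_samples,)
    /time_axis                float64 (n_samples,)  picoseconds
    /meta                     attrs: step_um, theta_deg, rotation_deg,
                              n_average, medium, seed, pixel_order

Round trips are lossless: arrays bit-identical, metadata field-by-field.
"""

from __future__ import annotations

import logging

import h5py
import numpy as np

from .forward_sim import CHANNELS, ScanCube, ScanMeta

log = logging.getLogger(__name__)

_META_FIELDS = ("step_um", "theta_deg", "rotation_deg", "n_average",
                "medium", "seed", "pixel_order")


class SchemaError(ValueError):
    """A scan file does not match the container schema."""


def write_scan(cube: ScanCube, path) -> None:
    """Write a ScanCube to ``path`` (HDF5, schema in the module docstring)."""
    with h5py.File(path, "w") as fh:
        g = fh.create_group("channels")
        for ch in CHANNELS:
            g.create_dataset(ch, data=cube.channels[ch])
        r = fh.create_group("references")
        for name, trace in cube.references.items():
            r.create_dataset(name, data=trace)
        fh.create_dataset("time_axis", data=cube.t_ps)
        m = fh.create_group("meta")
        for f in _META_FIELDS:
            m.attrs[f] = getattr(cube.meta, f)
    log.info("wrote scan cube %s (%dx%d pixels)", path, *cube.shape)


def read_scan(path) -> ScanCube:
    """Read a ScanCube; missing groups or length mismatches raise
    :class:`SchemaError` naming the offending group."""
    with h5py.File(path, "r") as fh:
        if "channels" not in fh:
            raise SchemaError("missing group /channels")
        missing = [ch for ch in CHANNELS if ch not in fh["channels"]]
        if missing:
            raise SchemaError(
                "missing channel group(s): " + ", ".join(f"/channels/{c}" for c in missing)
            )
        if "time_axis" not in fh:
            raise SchemaError("missing dataset /time_axis")
        t = fh["time_axis"][:]
        channels = {}
        for ch in CHANNELS:
            arr = fh["channels"][ch][:]
            if arr.ndim != 3 or arr.shape[2] != t.size:
                raise SchemaError(
                    f"/channels/{ch} has shape {arr.shape}; last axis must match "
                    f"time_axis length {t.size}"
                )
            channels[ch] = arr
        references = {}
        if "references" in fh:
            for name in fh["references"]:
                ref = fh["references"][name][:]
                if ref.shape != (t.size,):
                    raise SchemaError(
                        f"/references/{name} length {ref.shape} != time axis {t.size}"
                    )
                references[name] = ref
        if "meta" not in fh:
            raise SchemaError("missing group /meta")
        attrs = fh["meta"].attrs
        missing_meta = [f for f in _META_FIELDS if f not in attrs]
        if missing_meta:
            raise SchemaError("missing /meta attribute(s): " + ", ".join(missing_meta))
        meta = ScanMeta(
            step_um=float(attrs["step_um"]),
            theta_deg=float(attrs["theta_deg"]),
            rotation_deg=float(attrs["rotation_deg"]),
            n_average=int(attrs["n_average"]),
            medium=str(attrs["medium"]),
            seed=int(attrs["seed"]),
            pixel_order=str(attrs["pixel_order"]),
        )
    return ScanCube(channels=channels, references=references, t_ps=t, meta=meta)
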
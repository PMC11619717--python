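"""Rendering and per-tissue-class statistics of derived images.

The phantom's label map is the ground truth the instrument never sees;
comparing image values per class turns the qualitative colour reading of
polarimetric images ("strong reflection = cancer, weak = fat") into
numbers: per-class moments and a symmetric contrast index
(mean_a − mean_b)/(mean_a + mean_b) ∈ [−1, 1].
"""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile

from .phantom import LabelMap, TissueClass
from .spectra import PowerImage

log = logging.getLogger(__name__)


def _values(image) -> np.ndarray:
    if isinstance(image, PowerImage):
        return image.values
    return np.asarray(image, dtype=float)


def region_stats(image, labels: LabelMap) -> pd.DataFrame:
    """Per-class pixel statistics of an image against the label map.

    Returns a DataFrame indexed by class name with columns ``n_pixels``,
    ``mean``, ``std``, ``min``, ``max``, ``n_nan``.  NaN pixels are
    excluded from the moments and counted.
    """
    values = _values(image)
    if values.shape != labels.shape:
        raise ValueError(
            f"image shape {values.shape} does not match label map {labels.shape}"
        )
    rows = []
    for code in np.unique(labels.classes):
        cls = TissueClass(int(code))
        sel = values[labels.classes == code]
        finite = sel[np.isfinite(sel)]
        rows.append({
            "tissue": cls.name.lower(),
            "n_pixels": int(sel.size),
            "mean": float(finite.mean()) if finite.size else np.nan,
            "std": float(finite.std()) if finite.size else np.nan,
            "min": float(finite.min()) if finite.size else np.nan,
            "max": float(finite.max()) if finite.size else np.nan,
            "n_nan": int(sel.size - finite.size),
        })
    return pd.DataFrame(rows).set_index("tissue")


def class_contrast(stats: pd.DataFrame, a: TissueClass | str, b: TissueClass | str) -> float:
    """Symmetric contrast (mean_a − mean_b)/(mean_a + mean_b).

    Antisymmetric under swapping the classes; undefined (raises) when the
    mean sum is non-positive.
    """
    def _name(c):
        return c.name.lower() if isinstance(c, TissueClass) else str(c).lower()

    na, nb = _name(a), _name(b)
    for name in (na, nb):
        if name not in stats.index:
            raise ValueError(f"class {name!r} not present in the statistics table")
    ma, mb = float(stats.loc[na, "mean"]), float(stats.loc[nb, "mean"])
    denom = ma + mb
    if not denom > 0:
        raise ValueError(
            f"contrast undefined: mean({na}) + mean({nb}) = {denom} <= 0"
        )
    return (ma - mb) / denom


def render_image(image, out_path, colormap: str = "jet", title: str | None = None) -> None:
    """Write an image as 32-bit float TIFF plus an 8-bit PNG preview.

    The preview uses a jet-like colormap with a colorbar (the display
    convention of polarimetric THz figures); normalisation limits are the
    finite data range and are recorded in the log.
    """
    values = _values(image)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("cannot render an all-NaN image")
    out_path = str(out_path)
    tiff_path = out_path if out_path.endswith((".tif", ".tiff")) else out_path + ".tif"
    tifffile.imwrite(tiff_path, values.astype(np.float32))
    vmin, vmax = float(finite.min()), float(finite.max())
    png_path = tiff_path.rsplit(".", 1)[0] + ".png"
    fig, ax = plt.subplots(figsize=(4, 3.2))
    im = ax.imshow(values, cmap=colormap, vmin=vmin, vmax=vmax)
    fig.colorbar(im, ax=ax, shrink=0.85)
    if title:
        ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    log.info("rendered %s (range [%g, %g]) and preview %s", tiff_path, vmin, vmax, png_path)
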
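"""Shared readers/writers: TIFF/PNG images, expression/survival tables, JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def read_image(path: str | Path, stack: bool = False):
    """Read a TIFF or PNG; multi-page TIFFs return a list of slices when
    ``stack`` is True, otherwise the first page."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        slices = [arr[i] for i in range(arr.shape[0])]
        return slices if stack else slices[0]
    return [arr] if stack else arr


def write_image(path: str | Path, img, stack: bool = False) -> None:
    path = Path(path)
    import tifffile

    if stack:
        tifffile.imwrite(
            path,
            np.stack([np.asarray(s, np.float32) for s in img]),
            photometric="minisblack",
        )
    else:
        tifffile.imwrite(path, np.asarray(img, np.float32), photometric="minisblack")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    """Survival TSV with columns sample_id, time, event."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("sample_id")[["time", "event"]]


def write_json(path: str | Path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o).__name__)

    Path(path).write_text(json.dumps(obj, indent=1, default=_default, sort_keys=True))
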
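"""Movie/image I/O: multi-page TIFF with a JSON metadata sidecar.

Pixel data are stored as a (T, C, H, W) float32 TIFF stack.  Imaging
metadata (channel labels, pixel size, frame interval, frame times) are
embedded in the TIFF description tag and duplicated in a ``.json``
sidecar next to the file, which additionally carries the imaging
configuration and, for synthetic data, the ground-truth record.  On
load the two sources are cross-checked; a conflict is an error naming
both values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import GroundTruth, ImagingConfig, Movie

__all__ = ["save_movie", "load_movie", "sidecar_path"]


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def save_movie(movie: Movie, path: str | Path,
               config: ImagingConfig | None = None,
               ground_truth: GroundTruth | None = None) -> Path:
    """Write a movie as float32 TIFF plus JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "channels": list(movie.channels),
        "pixel_size_nm": movie.pixel_size_nm,
        "frame_interval_s": movie.frame_interval_s,
        "times_s": [float(t) for t in movie.times_s],
    }
    tifffile.imwrite(path, movie.data.astype(np.float32),
                     photometric="minisblack",
                     description=json.dumps(meta))
    sidecar = dict(meta)
    if config is not None:
        sidecar["imaging_config"] = config.to_dict()
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth.to_dict()
    sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def load_movie(path: str | Path,
               pixel_size_nm: float | None = None) -> Movie:
    """Read a movie written by :func:`save_movie` (or any TIFF stack).

    Metadata come from the TIFF description tag and/or the JSON sidecar;
    when both state a pixel size they must agree.  A stack with no pixel
    size anywhere requires ``pixel_size_nm``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    tag_meta: dict = {}
    try:
        parsed = json.loads(desc)
        if isinstance(parsed, dict):
            tag_meta = parsed
    except (json.JSONDecodeError, TypeError):
        pass
    side = sidecar_path(path)
    side_meta = json.loads(side.read_text()) if side.exists() else {}

    for key in ("pixel_size_nm", "frame_interval_s"):
        if key in tag_meta and key in side_meta:
            a, b = tag_meta[key], side_meta[key]
            if not np.isclose(a, b):
                raise ValueError(
                    f"metadata conflict for {key}: TIFF tag says {a}, "
                    f"sidecar says {b}")
    meta = {**side_meta, **tag_meta}
    px = meta.get("pixel_size_nm", pixel_size_nm)
    if px is None:
        raise ValueError("no pixel size in file metadata and none supplied")
    channels = tuple(meta.get("channels", []))
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        # ambiguous (T, H, W) vs (C, H, W): use channel labels to decide
        if channels and data.shape[0] == len(channels):
            data = data[None]
        else:
            data = data[:, None]
    if not channels:
        channels = tuple(f"ch{i}" for i in range(data.shape[1]))
    interval = float(meta.get("frame_interval_s", 1.0))
    times = meta.get("times_s")
    return Movie(data, channels, float(px), interval,
                 times_s=np.asarray(times, dtype=float) if times else None)
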
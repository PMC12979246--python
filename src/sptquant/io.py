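"""File formats: multi-page TIFF movies, CSV tables, JSON summaries.

Physical metadata (pixel size, frame interval) is carried in the run
configuration, never in TIFF tags, to avoid dialect ambiguity.  CSVs are
comma-separated UTF-8 with a header row and floats at 9 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import GroundTruthTrajectory, SyntheticMovie

FLOAT_FORMAT = "%.9g"


def write_movie(path, frames) -> None:
    """Write a stack (array or SyntheticMovie) as multi-page 16-bit TIFF.

    Float stacks (e.g. stripe recordings) are rounded and clipped to the
    16-bit range.
    """
    arr = np.asarray(getattr(frames, "frames", frames))
    if arr.ndim != 3:
        raise ValueError("movie must be a (n_frames, H, W) stack")
    if arr.dtype != np.uint16:
        arr = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def read_movie(path, pixel_size: float = 0.096,
               frame_interval: float = 0.020) -> SyntheticMovie:
    """Read a multi-page grayscale TIFF; metadata comes from the caller."""
    try:
        with tifffile.TiffFile(str(path)) as tif:
            pages = [page.asarray() for page in tif.pages]
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise ValueError(f"cannot read movie {path}: {exc}") from exc
    if not pages:
        raise ValueError(f"{path}: file contains no image pages")
    shape = pages[0].shape
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise ValueError(
                f"{path}: page {i} is not 2-D grayscale (shape {page.shape})")
        if page.shape != shape:
            raise ValueError(f"{path}: page {i} shape {page.shape} differs "
                             f"from page 0 shape {shape}")
    arr = np.stack(pages)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: expected integer grayscale pixels")
    return SyntheticMovie(frames=arr, pixel_size=pixel_size,
                          frame_interval=frame_interval)


def write_truth_csv(trajectories: list[GroundTruthTrajectory], path) -> None:
    rows = []
    for tr in trajectories:
        for f in range(tr.positions.shape[0]):
            rows.append((tr.molecule_id, f, tr.positions[f, 0],
                         tr.positions[f, 1], tr.state, int(tr.emitting[f])))
    df = pd.DataFrame(rows, columns=["molecule_id", "frame", "x_um", "y_um",
                                     "state", "emitting"])
    write_table(df, path)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
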
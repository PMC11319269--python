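"""File formats and the fixed color convention.

CSV is the canonical matrix format (human-diffable, language-neutral);
PNG export is derived output only and is never parsed back.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InvalidCodeError, MalformedFileError
from .population_model import PopulationGrid
from .signal_fields import SignalField

__all__ = [
    "PALETTE",
    "read_pattern_csv",
    "write_pattern_csv",
    "read_field_csv",
    "write_field_csv",
    "export_png",
    "write_manifest",
]

#: fate code -> RGB, following the figure convention:
#: 1 SC1 magenta, 2 A blue, 3 B cyan, 4 SC2 green, 5 C yellow, 6 D red.
PALETTE: dict[int, tuple[int, int, int]] = {
    1: (255, 0, 255),
    2: (0, 0, 255),
    3: (0, 255, 255),
    4: (0, 160, 0),
    5: (255, 220, 0),
    6: (255, 0, 0),
}


def _load_matrix(path) -> np.ndarray:
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # empty-file notice
            arr = np.loadtxt(path, delimiter=",", ndmin=2)
    except (OSError, ValueError) as exc:
        raise MalformedFileError(f"cannot parse {path}: {exc}") from exc
    if arr.size == 0:
        raise MalformedFileError(f"{path} holds an empty matrix")
    return arr


def read_pattern_csv(path) -> PopulationGrid:
    """Load a cellular pattern (integer codes 1-6) from CSV."""
    arr = _load_matrix(path)
    if not np.allclose(arr, np.round(arr)):
        raise MalformedFileError(f"{path} holds non-integer codes")
    codes = arr.astype(np.int64)
    if codes.size and not np.isin(codes, range(1, 7)).all():
        bad = sorted(set(np.unique(codes)) - set(range(1, 7)))
        raise InvalidCodeError(f"codes outside 1..6 in {path}: {bad}")
    if codes.shape[0] != codes.shape[1]:
        raise MalformedFileError(f"{path} is not square: {codes.shape}")
    return PopulationGrid(codes)


def write_pattern_csv(grid: PopulationGrid, path) -> None:
    np.savetxt(path, grid.codes, fmt="%d", delimiter=",")


def read_field_csv(path, scale_max: float = 5.0, channel_id: int = 1) -> SignalField:
    """Load a signal plane (numeric matrix) from CSV."""
    arr = _load_matrix(path)
    if arr.shape[0] != arr.shape[1]:
        raise MalformedFileError(f"{path} is not square: {arr.shape}")
    return SignalField(arr, scale_max=scale_max, channel_id=channel_id)


def write_field_csv(f: SignalField, path) -> None:
    np.savetxt(path, f.values, fmt="%.8g", delimiter=",")


def export_png(obj, path, palette: dict[int, tuple] | None = None) -> None:
    """Write a one-pixel-per-site image: palette colors for code grids,
    grayscale (min -> black, max -> white) for signal fields."""
    if isinstance(obj, PopulationGrid):
        pal = palette or PALETTE
        rgb = np.zeros(obj.codes.shape + (3,), dtype=np.uint8)
        for code, color in pal.items():
            rgb[obj.codes == code] = color
        Image.fromarray(rgb, mode="RGB").save(path)
        return
    if isinstance(obj, SignalField):
        v = obj.values
        lo, hi = v.min(), v.max()
        gray = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
        Image.fromarray((gray * 255).astype(np.uint8), mode="L").save(path)
        return
    raise TypeError(f"cannot export {type(obj).__name__} as PNG")


def write_manifest(path, config, seed) -> None:
    """Record config + seed + package version next to an output file."""
    from . import __version__

    Path(path).write_text(json.dumps(
        {"config": config.to_dict(), "seed": seed, "version": __version__},
        indent=2, sort_keys=True) + "\n")
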
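"""Fast analytic stand-ins for tests and demos.

These fixtures satisfy the pattern-class definitions by construction (a
lattice of Gaussian bumps for "spot", thresholded sine bands for "stripe",
...) without running the PDE or the SSA.
"""

from __future__ import annotations

import numpy as np

from .errors import UnknownKindError
from .population_model import PopulationGrid
from .signal_fields import SignalField

__all__ = ["make_fixture"]


def _bump_lattice(sz: int, n_per_row: int = 4, sigma_frac: float = 0.06):
    y, x = np.mgrid[0:sz, 0:sz].astype(float)
    centers = (np.arange(n_per_row) + 0.5) * sz / n_per_row
    field = np.zeros((sz, sz))
    sigma = sigma_frac * sz
    for cy in centers:
        for cx in centers:
            field += np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma ** 2))
    return field


def make_fixture(kind: str, sz: int = 60, seed: int | None = None):
    """Deterministic (seeded) fixture of the requested kind.

    Signal-field kinds: ``spot``, ``reverse_spot``, ``stripe``,
    ``gaussian``, ``sinusoidal`` (values already on the (0, 5) scale).
    Grid kind: ``random_pattern`` (codes uniform over 1-6).
    """
    rng = np.random.default_rng(seed)
    if kind == "spot":
        v = _bump_lattice(sz)
        return SignalField(5.0 * v / v.max())
    if kind == "reverse_spot":
        v = _bump_lattice(sz)
        return SignalField(5.0 * (1.0 - v / v.max()))
    if kind == "stripe":
        x = np.tile(np.arange(sz, dtype=float), (sz, 1))
        v = 0.5 * (1.0 + np.sin(2 * np.pi * 4.25 * x / sz))
        return SignalField(5.0 * v)
    if kind == "gaussian":
        y, x = np.mgrid[0:sz, 0:sz].astype(float)
        cx, cy = 0.4 * sz, 0.3 * sz
        sigma = 0.02 * sz + 1.0
        v = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma ** 2))
        return SignalField(5.0 * v)
    if kind == "sinusoidal":
        x = np.tile(np.arange(sz, dtype=float), (sz, 1))
        v = np.sin(4.5 * x)
        return SignalField(2.5 * (v + 1.0))
    if kind == "random_pattern":
        return PopulationGrid(rng.integers(1, 7, size=(sz, sz)))
    raise UnknownKindError(f"unknown fixture kind {kind!r}")
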
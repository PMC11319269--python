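"""Inverse route: from a cellular pattern back to its driving signals.

Each differentiated phenotype pins the local signal pair at an extreme
(A: both high, B: both low, C: s1 low / s2 high, D: s1 high / s2 low); stem
pixels carry no directional information.  Reconstructing the two binary
signal planes pixel-by-pixel and classifying them recovers the *class*
(spot / reverse spot / stripe) of each driving signal, provided the signals
came from the known Turing family.

The reproducibility analysis compares stochastic realizations of the
population algorithm against a deterministic reference pattern built by
thresholding each signal at half its maximum and mapping the four extreme
pairs to fates; the resemblance score is the fraction of identical pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .errors import (
    InsufficientInformationError,
    InvalidCodeError,
    ShapeMismatchError,
)
from .population_model import Algorithm1Result, PopulationGrid, run_algorithm1
from .signal_fields import SignalField, classify_pattern

__all__ = [
    "ReconstructedPlanes",
    "ScoreReport",
    "reconstruct_signals",
    "classify_reconstruction",
    "reference_pattern",
    "resemblance_score",
    "score_replicates",
]

#: code -> (s1, s2) in {0, 0.5, 1}; 0.5 marks "indeterminate" (stem pixel)
_CODE_TO_PLANES = {
    1: (0.5, 0.5),
    2: (1.0, 1.0),
    3: (0.0, 0.0),
    4: (0.5, 0.5),
    5: (0.0, 1.0),
    6: (1.0, 0.0),
}

#: extreme (s1_high, s2_high) pair -> fate code of the reference pattern
_EXTREME_TO_CODE = {
    (True, True): 2,    # A
    (False, False): 3,  # B
    (False, True): 5,   # C
    (True, False): 6,   # D
}


@dataclass
class ReconstructedPlanes:
    """Two sz x sz planes with values in {0, 0.5, 1}."""

    s1_plane: np.ndarray
    s2_plane: np.ndarray


@dataclass
class ScoreReport:
    """Per-replicate resemblance scores with summary statistics."""

    scores: list[float]

    @property
    def median(self) -> float:
        return float(np.median(self.scores))

    @property
    def quartiles(self) -> tuple[float, float]:
        return (float(np.percentile(self.scores, 25)),
                float(np.percentile(self.scores, 75)))


def reconstruct_signals(pattern: PopulationGrid) -> ReconstructedPlanes:
    """Pure pixel-wise map from fate codes to the two binary signal planes."""
    codes = pattern.codes
    bad = set(np.unique(codes)) - set(_CODE_TO_PLANES)
    if bad:
        raise InvalidCodeError(f"invalid codes in pattern: {sorted(bad)}")
    s1 = np.empty(codes.shape)
    s2 = np.empty(codes.shape)
    for code, (v1, v2) in _CODE_TO_PLANES.items():
        sel = codes == code
        s1[sel] = v1
        s2[sel] = v2
    return ReconstructedPlanes(s1, s2)


def classify_reconstruction(
    planes: ReconstructedPlanes,
    max_missing: float = 0.9,
) -> tuple[str, str]:
    """Pattern class of each reconstructed plane.

    Pixels valued 0.5 are treated as missing; the {0, 1} skeleton goes
    through the steady-field classifier.  Raises
    :class:`InsufficientInformationError` when more than ``max_missing``
    of the pixels are indeterminate."""
    out = []
    for plane in (planes.s1_plane, planes.s2_plane):
        missing = plane == 0.5
        if missing.mean() > max_missing:
            raise InsufficientInformationError(
                f"{missing.mean():.0%} of pixels are stem-valued")
        out.append(classify_pattern(SignalField(plane, scale_max=1.0),
                                    missing=missing))
    return tuple(out)


def reference_pattern(s1: SignalField, s2: SignalField) -> PopulationGrid:
    """Deterministic pattern from half-max thresholded signals.

    Each signal is thresholded at half its maximum value -- the top of its
    decision scale (5 for planes scaled to (0, 5)): values below go to 0,
    values at or above go to the maximum.  The four extreme pairs map to
    the differentiated fates regardless of lineage placement:
    (hi, hi) -> A, (lo, lo) -> B, (lo, hi) -> C, (hi, lo) -> D.
    """
    if s1.values.shape != s2.values.shape:
        raise ShapeMismatchError("signal planes must share a shape")
    hi1 = s1.values >= 0.5 * s1.scale_max
    hi2 = s2.values >= 0.5 * s2.scale_max
    codes = np.empty(hi1.shape, dtype=np.int64)
    for (h1, h2), code in _EXTREME_TO_CODE.items():
        codes[(hi1 == h1) & (hi2 == h2)] = code
    return PopulationGrid(codes)


def resemblance_score(pattern: PopulationGrid,
                      reference: PopulationGrid) -> float:
    """Fraction of pixels whose codes are identical."""
    if pattern.codes.shape != reference.codes.shape:
        raise ShapeMismatchError("patterns must share a shape")
    return float((pattern.codes == reference.codes).mean())


def score_replicates(
    config: RunConfig,
    signals: tuple[SignalField, SignalField],
    n_replicates: int = 5,
    seed: int | None = None,
    keep_runs: bool = False,
) -> ScoreReport | tuple[ScoreReport, list[Algorithm1Result]]:
    """Run the population algorithm ``n_replicates`` times against fixed
    signal planes and score each realization against the half-max reference.

    Replicate seeds derive from ``seed``.  The painting scope is taken from
    ``config`` (the reference-comparison protocol uses population-scoped,
    offspring-only painting; see docs/methods.md).
    """
    if n_replicates < 1:
        raise InvalidCodeError("n_replicates must be >= 1")
    ref = reference_pattern(*signals)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    scores = []
    runs = []
    for child in ss.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31 - 1))
        res = run_algorithm1(config, seed=rep_seed, signals=signals)
        scores.append(resemblance_score(res.grid, ref))
        if keep_runs:
            runs.append(res)
    report = ScoreReport(scores)
    return (report, runs) if keep_runs else report
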
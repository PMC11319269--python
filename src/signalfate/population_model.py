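"""Population-level pattern formation.

A ``sz x sz`` plane of randomly seeded stem cells (types SC1/SC2) is exposed
to two frozen or co-evolving signal planes on the (0, 5) scale.  Each cell
cycle the per-site determinant switches are reset to the stem state, evolved
stochastically under their signal-biased rates, and the attractor each site
would settle into (its *virtual fate*) is recorded into per-type 6x6 look-up
tables indexed by the binned local (s1, s2).  Emergence probabilities are
re-evaluated on a fixed cadence; when their maximum change drops below
epsilon the loop stops and the plane is painted from the tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .config import RunConfig, SignalSpec
from .errors import (
    InvalidSpecError,
    NonConvergenceError,
    OutOfRangeError,
    ShapeMismatchError,
)
from .fate_switch import (
    FATES,
    SwitchParams,
    eta,
    zeta,
    stem_state,
)
from .signal_fields import (
    SignalField,
    StaticProfileSpec,
    integrate_rd,
    normalize_to_scale,
    preset,
    static_profile,
)

__all__ = [
    "PopulationGrid",
    "FateLookupTable",
    "ConvergenceState",
    "Algorithm1Result",
    "init_population",
    "bin_signal",
    "bin_signal_array",
    "alpha_fields",
    "run_cycle",
    "record_virtual_fates",
    "emergence_probabilities",
    "run_algorithm1",
    "new_lookup_tables",
    "signal_pair_combinations",
]

N_BINS = 6
_SCALE = 5.0

#: fate codes per lineage as (stem, high-x, high-y)
LINEAGE_CODES = {1: (1, 2, 3), 2: (4, 5, 6)}


@dataclass
class PopulationGrid:
    """Square matrix of cell-type codes 1-6."""

    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2 or self.codes.shape[0] != self.codes.shape[1]:
            raise InvalidSpecError("codes must form a square matrix")
        if self.codes.size and not np.isin(self.codes, range(1, 7)).all():
            raise InvalidSpecError("codes must lie in 1..6")

    @property
    def sz(self) -> int:
        return self.codes.shape[0]


@dataclass
class FateLookupTable:
    """6x6 virtual-division counts for one cell type, indexed by the
    binned (s1, s2) pair on the (0, 5) scale (rows: s1, columns: s2)."""

    fate_code: int
    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((N_BINS, N_BINS), dtype=np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def new_lookup_tables() -> dict[int, FateLookupTable]:
    return {code: FateLookupTable(code) for code in range(1, 7)}


@dataclass
class ConvergenceState:
    """Bookkeeping of the probability-convergence loop."""

    pb_old: np.ndarray | None = None
    pb_new: np.ndarray | None = None
    diff: float = 10_000.0  # start arbitrarily large to force iterations
    epsilon: float = 0.0025

    @property
    def converged(self) -> bool:
        return self.diff < self.epsilon


@dataclass
class Algorithm1Result:
    grid: PopulationGrid
    tables: dict[int, FateLookupTable]
    diff_trace: list[float]
    n_cycles: int
    lineages: np.ndarray
    s1: SignalField
    s2: SignalField
    pb: np.ndarray  # final per-type per-site probabilities (6, sz, sz)


def init_population(sz: int, fraction_sc1: float = 0.5,
                    seed: int | None = None) -> PopulationGrid:
    """Independent Bernoulli placement of SC1 (code 1) vs SC2 (code 4)."""
    if not 0.0 <= fraction_sc1 <= 1.0:
        raise InvalidSpecError("fraction_sc1 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sc1 = rng.random((sz, sz)) < fraction_sc1
    return PopulationGrid(np.where(sc1, 1, 4))


def bin_signal(s: float) -> int:
    """Bin index 0-5 of a concentration on (0, 5): floor(s*6/5), the top
    edge clamped into the last bin."""
    if s < 0.0 or s > _SCALE:
        raise OutOfRangeError(f"signal {s} outside [0, {_SCALE}]")
    return min(int(s * N_BINS / _SCALE), N_BINS - 1)


def bin_signal_array(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if (s < 0.0).any() or (s > _SCALE).any():
        raise OutOfRangeError("signal values outside [0, 5]")
    return np.minimum((s * N_BINS / _SCALE).astype(np.int64), N_BINS - 1)


def alpha_fields(lineages: np.ndarray, s1: np.ndarray, s2: np.ndarray,
                 params: SwitchParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-site signal-biased self-activation rates (vectorized
    :func:`fate_switch.alpha_rates`)."""
    e1, e2 = eta(s1, params), eta(s2, params)
    z1, z2 = zeta(s1, params), zeta(s2, params)
    if params.scaling == "product":
        e1, z1 = e1 / params.signal_gain, z1 / params.signal_gain
    ax = np.where(lineages == 1,
                  params.alpha0_x + e1 * e2,
                  params.alpha0_x + e2 * z1)
    ay = np.where(lineages == 1,
                  params.alpha0_y + z1 * z2,
                  params.alpha0_y + e1 * z2)
    return ax, ay


def _classify_settled(x, y, lineages, rel_tol):
    """Vectorized settled-point fate map (stem band + larger determinant)."""
    top = np.maximum(np.maximum(x, y), 1e-12)
    stem = np.abs(x - y) <= rel_tol * top
    hi_x = ~stem & (x > y)
    codes = np.where(lineages == 1, 1, 4)
    codes = np.where(hi_x, np.where(lineages == 1, 2, 5), codes)
    codes = np.where(~stem & ~hi_x, np.where(lineages == 1, 3, 6), codes)
    return codes


def run_cycle(
    lineages: np.ndarray,
    s1: np.ndarray,
    s2: np.ndarray,
    params: SwitchParams,
    steps: int = 100,
    dt_step: float = 0.12,
    seed: int | None = None,
    omega_det: float = 1.0,
    leap_dt: float = 0.05,
    t_descend: float = 60.0,
    fate_rel_tol: float = 0.2,
    stem_xy: tuple[float, float] | None = None,
) -> np.ndarray:
    """One cell cycle: evolve each site's determinants stochastically from
    the stem state for ``steps`` steps, then assess the virtual fate of each
    site by deterministic descent of its endpoint.  The resident stem types
    (``lineages``) are not changed.  Returns the per-site fate codes."""
    if lineages.shape != np.shape(s1) or np.shape(s1) != np.shape(s2):
        raise ShapeMismatchError("lineages and signal planes must align")
    ax, ay = alpha_fields(lineages, s1, s2, params)
    x0, y0 = stem_xy if stem_xy is not None else stem_state(params)
    X = np.full(lineages.size, int(round(x0 * omega_det)), dtype=np.int64)
    Y = np.full(lineages.size, int(round(y0 * omega_det)), dtype=np.int64)
    t_total = steps * dt_step
    if t_total > 0:
        _kernels.determinant_leap(
            X, Y, ax.ravel().astype(float), ay.ravel().astype(float),
            float(params.n), float(params.beta ** params.n),
            float(params.k1), float(params.k2),
            float(params.gamma1), float(params.gamma2),
            float(omega_det), float(t_total), float(leap_dt),
            np.uint32(seed if seed is not None else 0),
        )
        xf, yf = _kernels.rk4_descend(
            X / omega_det, Y / omega_det,
            ax.ravel(), ay.ravel(),
            params.n, params.beta ** params.n, params.k1, params.k2,
            params.gamma1, params.gamma2, t_total=t_descend)
    else:  # zero-length cycle: states unchanged, fate read off the start
        xf, yf = X / omega_det, Y / omega_det
    return _classify_settled(xf, yf, lineages.ravel(), fate_rel_tol) \
        .reshape(lineages.shape)


def record_virtual_fates(
    tables: dict[int, FateLookupTable],
    fates: np.ndarray,
    s1: np.ndarray,
    s2: np.ndarray,
) -> dict[int, FateLookupTable]:
    """Increment ``tables[fate][bin(s1), bin(s2)]`` for every site."""
    b1 = bin_signal_array(s1).ravel()
    b2 = bin_signal_array(s2).ravel()
    f = np.asarray(fates).ravel()
    for code in range(1, 7):
        sel = f == code
        if sel.any():
            np.add.at(tables[code].counts, (b1[sel], b2[sel]), 1)
    return tables


def emergence_probabilities(
    tables: dict[int, FateLookupTable],
    population_size: int,
    per_bin: bool = False,
) -> dict[int, np.ndarray]:
    """Per-type 6x6 probabilities.

    Default: counts divided by ``population_size`` (the recorded-event
    divisor the caller chooses).  With ``per_bin=True``: counts divided by
    the total events in the same bin across the lineage's three tables
    (the variant used for painting); unpopulated bins give 0.
    """
    if population_size <= 0:
        raise InvalidSpecError("population_size must be positive")
    if not per_bin:
        return {c: tables[c].counts / float(population_size)
                for c in range(1, 7)}
    out = {}
    for lin, codes in LINEAGE_CODES.items():
        tot = sum(tables[c].counts for c in codes).astype(float)
        safe = np.where(tot > 0, tot, 1.0)
        for c in codes:
            out[c] = np.where(tot > 0, tables[c].counts / safe, 0.0)
    return out


def _site_probabilities(tables, b1, b2, n_events):
    """(6, sz, sz) per-site pb from cumulative tables (event-normalized)."""
    pb = np.empty((6,) + b1.shape)
    for c in range(1, 7):
        pb[c - 1] = tables[c].counts[b1, b2] / float(n_events)
    return pb


def _resolve_signal(spec: SignalSpec, rd, sz, seed, t_end) -> SignalField:
    if spec.kind == "uniform":
        return SignalField(np.full((sz, sz), float(spec.value)))
    if spec.kind == "preset":
        rd = preset(spec.name)
        su, _ = integrate_rd(rd, t_end=t_end, seed=seed, sz=sz)
        f = su
    elif spec.kind == "static":
        f = static_profile(
            StaticProfileSpec(spec.profile, x_star=spec.x_star,
                              y_star=spec.y_star, sigma=spec.sigma, k=spec.k),
            sz)
    else:  # csv
        from .io import read_field_csv
        f = read_field_csv(spec.path)
        if f.sz != sz:
            raise ShapeMismatchError(
                f"signal CSV is {f.sz}x{f.sz}, expected {sz}x{sz}")
    if spec.kind != "csv" or spec.normalize:
        f = normalize_to_scale(f, _SCALE)
    return f


def _paint(tables, b1, b2, lineages, config, rng):
    """Paint the final plane from the look-up tables."""
    sz = b1.shape[0]
    counts = np.stack([tables[c].counts for c in range(1, 7)]).astype(float)
    if config.offspring_only:
        counts[[0, 3]] = 0.0  # mask the self-renewal rows (codes 1 and 4)

    def pick(weights, mode):
        if weights.sum() <= 0:
            return 0
        if mode == "sample":
            return int(rng.choice(6, p=weights / weights.sum())) + 1
        top = np.flatnonzero(weights == weights.max())
        return int(rng.choice(top)) + 1

    # per (scope, bin) decision cache so ties resolve once per bin
    out = np.zeros((sz, sz), dtype=np.int64)
    cache: dict[tuple, int] = {}
    for r in range(sz):
        for c in range(sz):
            lin = int(lineages[r, c])
            scope_codes = (range(6) if config.paint_scope == "population"
                           else [cd - 1 for cd in LINEAGE_CODES[lin]])
            key = (lin if config.paint_scope == "lineage" else 0,
                   b1[r, c], b2[r, c])
            if key in cache and config.paint_mode == "argmax":
                out[r, c] = cache[key]
                continue
            w = np.zeros(6)
            i1, i2 = b1[r, c], b2[r, c]
            sel = list(scope_codes)
            if counts[sel, i1, i2].sum() <= 0:
                # unpopulated bin: nearest populated bin by Manhattan distance
                pop = np.argwhere(counts[sel].sum(axis=0) > 0)
                if pop.size:
                    dist = np.abs(pop[:, 0] - i1) + np.abs(pop[:, 1] - i2)
                    near = pop[dist == dist.min()]
                    i1, i2 = near[rng.integers(len(near))]
            w[sel] = counts[sel, i1, i2]
            code = pick(w, config.paint_mode)
            if code == 0:  # nothing recorded anywhere in scope
                code = lin if config.paint_scope != "population" else 1
                code = LINEAGE_CODES[int(lineages[r, c])][0]
            if config.paint_mode == "argmax":
                cache[key] = code
            out[r, c] = code
    return PopulationGrid(out)


def run_algorithm1(
    config: RunConfig,
    seed: int | None = None,
    signals: tuple[SignalField, SignalField] | None = None,
) -> Algorithm1Result:
    """Full population loop: cycles of stochastic switch evolution, virtual
    fate recording, cadenced probability evaluation, convergence at
    ``diff < epsilon``, and final painting.  ``signals`` may supply
    ready-made (0, 5)-scaled planes, overriding the config's signal source.
    """
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    s_init, s_sig1, s_sig2, s_cycles, s_paint, s_coev = ss.spawn(6)

    def small(s):
        return int(s.generate_state(1)[0] % (2 ** 31 - 1))

    sz = config.sz
    if signals is not None:
        f1, f2 = signals
        if f1.sz != sz or f2.sz != sz:
            raise ShapeMismatchError("supplied signal planes must match sz")
    else:
        f1 = _resolve_signal(config.signal1, config.rd1, sz, small(s_sig1),
                             config.signal_t_end)
        f2 = _resolve_signal(config.signal2, config.rd2, sz, small(s_sig2),
                             config.signal_t_end)
    s1, s2 = f1.values, f2.values

    grid0 = init_population(sz, config.fraction_sc1, small(s_init))
    lineages = np.where(grid0.codes == 1, 1, 2)

    coevolve = config.signal_mode == "coevolve"
    if coevolve:
        rd1, rd2 = config.rd1, config.rd2
        if config.signal1.kind == "preset":
            rd1 = preset(config.signal1.name)
        if config.signal2.kind == "preset":
            rd2 = preset(config.signal2.name)
        SU1 = np.round(f1.values / _SCALE * rd1.su_max * config.omega).astype(np.int64)
        SV1 = np.round((rd1.B * SU1 / config.omega - 1.0).clip(0) * config.omega).astype(np.int64)
        SU2 = np.round(f2.values / _SCALE * rd2.su_max * config.omega).astype(np.int64)
        SV2 = np.round((rd2.B * SU2 / config.omega - 1.0).clip(0) * config.omega).astype(np.int64)

    tables = new_lookup_tables()
    conv = ConvergenceState(epsilon=config.epsilon)
    diff_trace: list[float] = []
    eval_every = max(1, config.eval_every_steps // max(config.cycle_steps, 1))
    cycle_rng = np.random.default_rng(small(s_cycles))
    coev_seed = small(s_coev)

    b1 = bin_signal_array(s1)
    b2 = bin_signal_array(s2)
    stem_xy = stem_state(config.switch)
    n_cycles = 0
    while not conv.converged:
        if n_cycles >= config.max_cycles:
            raise NonConvergenceError(
                f"no convergence after {n_cycles} cycles "
                f"(diff={conv.diff:.5f}, epsilon={config.epsilon})",
                diff_trace)
        if coevolve and n_cycles > 0:
            for (SU, SV, rd, ch) in ((SU1, SV1, rd1, 1), (SU2, SV2, rd2, 2)):
                _kernels.signal_leap(
                    SU, SV, rd.A, rd.B, rd.C, rd.gamma, rd.d, rd.h,
                    rd.su_max, config.omega,
                    config.coevolve_time_per_cycle, config.coevolve_dt,
                    np.uint32((coev_seed + 7 * n_cycles + ch) % (2 ** 31)))
            s1 = SU1 / config.omega / rd1.su_max * _SCALE
            s2 = SU2 / config.omega / rd2.su_max * _SCALE
            b1, b2 = bin_signal_array(s1), bin_signal_array(s2)

        fates = run_cycle(
            lineages, s1, s2, config.switch,
            steps=config.cycle_steps, dt_step=config.dt_step,
            seed=int(cycle_rng.integers(2 ** 31 - 1)),
            omega_det=config.omega_det, leap_dt=config.leap_dt,
            t_descend=config.t_descend, fate_rel_tol=config.fate_rel_tol,
            stem_xy=stem_xy)
        record_virtual_fates(tables, fates, s1, s2)
        n_cycles += 1

        if n_cycles % eval_every == 0:
            n_events = n_cycles * sz * sz
            pb = _site_probabilities(tables, b1, b2, n_events)
            if conv.pb_old is None:  # the algorithm starts from pb_old = 0
                conv.pb_old = np.zeros_like(pb)
            conv.diff = float(np.abs(pb - conv.pb_old).max())
            diff_trace.append(conv.diff)
            conv.pb_old = pb
            conv.pb_new = pb

    paint_rng = np.random.default_rng(small(s_paint))
    grid = _paint(tables, b1, b2, lineages, config, paint_rng)
    return Algorithm1Result(
        grid=grid, tables=tables, diff_trace=diff_trace, n_cycles=n_cycles,
        lineages=lineages, s1=SignalField(s1), s2=SignalField(s2),
        pb=conv.pb_new,
    )


def signal_pair_combinations() -> list[tuple[str, str]]:
    """The nine ordered combinations of the three steady-state signal
    classes."""
    kinds = ("spot", "reverse_spot", "stripe")
    return [(a, b) for a in kinds for b in kinds]
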
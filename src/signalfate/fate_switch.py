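"""Signal-biased tri-stable intracellular switch.

Two determinants x, y per stem cell obey

    dx/dt = alpha_x * x^n/(beta^n + x^n) + k1 * beta^n/(beta^n + y^n) - gamma1 x
    dy/dt = alpha_y * y^n/(beta^n + y^n) + k2 * beta^n/(beta^n + x^n) - gamma2 y

(Hill self-activation, mutual repression, linear degradation).  With the
baseline rates the system is tri-stable: a stem state on the diagonal and two
differentiated states (high-x / high-y).  Environmental signals (s1, s2) on
the (0, 5) scale bias the self-activation rates through the increasing and
decreasing Hill transfer functions ``eta`` and ``zeta``:

    lineage 1:  alpha_x = alpha0 + eta(s1) eta(s2),  alpha_y = alpha0 + zeta(s1) zeta(s2)
    lineage 2:  alpha_x = alpha0 + eta(s2) zeta(s1), alpha_y = alpha0 + eta(s1) zeta(s2)

``eta`` and ``zeta`` each carry a gain factor (default 20), so the products
range up to 400 and can dominate the basal rate.  High-x resolves to offspring
A (lineage 1) or C (lineage 2); high-y to B or D; the diagonal state to
self-renewal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import InvalidSpecError

__all__ = [
    "SwitchParams",
    "DeterminantState",
    "SignalPair",
    "Fate",
    "FATES",
    "FATE_BY_CODE",
    "eta",
    "zeta",
    "alpha_rates",
    "switch_rhs",
    "find_attractors",
    "stem_state",
    "classify_fate",
    "fate_from_point",
    "phase_field",
]


@dataclass(frozen=True)
class SwitchParams:
    """Constants of the intracellular switch (defaults are the study values)."""

    n: float = 4.0
    beta: float = 42.0
    k1: float = 30.0
    k2: float = 30.0
    gamma1: float = 0.38
    gamma2: float = 0.38
    alpha0_x: float = 30.0
    alpha0_y: float = 30.0
    K1: float = 2.5
    K2: float = 2.5
    signal_gain: float = 20.0
    #: 'product': the gain multiplies each eta*zeta product once (bias tops
    #: out at signal_gain).  'per_function': the gain multiplies eta and zeta
    #: individually, so the products reach gain^2 = 400.  The product reading
    #: keeps a lineage neutral whenever the other lineage is being driven
    #: (e.g. SC1 at (0, 5)), which the cruciform fate plane requires; the
    #: per-function reading maximizes the corner biases but destroys that
    #: neutrality.
    scaling: str = "product"

    def __post_init__(self):
        for name in (
            "beta", "k1", "k2", "gamma1", "gamma2",
            "alpha0_x", "alpha0_y", "K1", "K2", "signal_gain",
        ):
            if not getattr(self, name) > 0:
                raise InvalidSpecError(f"SwitchParams.{name} must be > 0")
        if self.n < 1:
            raise InvalidSpecError("Hill coefficient n must be >= 1")
        if self.scaling not in ("per_function", "product"):
            raise InvalidSpecError(f"unknown scaling {self.scaling!r}")


@dataclass
class DeterminantState:
    """Per-cell determinant pair and the lineage the switch belongs to."""

    x: float
    y: float
    lineage: int = 1

    def __post_init__(self):
        if self.x < 0 or self.y < 0:
            raise InvalidSpecError("determinant concentrations must be >= 0")
        if self.lineage not in (1, 2):
            raise InvalidSpecError("lineage must be 1 or 2")


@dataclass(frozen=True)
class SignalPair:
    """A pair of signal concentrations on the (0, 5) decision scale."""

    s1: float
    s2: float

    def __post_init__(self):
        if not (0.0 <= self.s1 <= 5.0 and 0.0 <= self.s2 <= 5.0):
            raise InvalidSpecError("signals must lie in [0, 5]")


@dataclass(frozen=True)
class Fate:
    """One of the six phenotypes with its fixed code and display color."""

    label: str
    code: int
    color: str


FATES: dict[str, Fate] = {
    "SC1": Fate("SC1", 1, "magenta"),
    "A": Fate("A", 2, "blue"),
    "B": Fate("B", 3, "cyan"),
    "SC2": Fate("SC2", 4, "green"),
    "C": Fate("C", 5, "yellow"),
    "D": Fate("D", 6, "red"),
}
FATE_BY_CODE: dict[int, Fate] = {f.code: f for f in FATES.values()}

#: (stem, high-x, high-y) fate labels per lineage.
_LINEAGE_TRIPLE = {1: ("SC1", "A", "B"), 2: ("SC2", "C", "D")}


def eta(s, params: SwitchParams = SwitchParams()):
    """Increasing signal transfer: ``gain * s^2 / (K1^2 + s^2)``."""
    s = np.asarray(s, dtype=float)
    out = params.signal_gain * s ** 2 / (params.K1 ** 2 + s ** 2)
    return float(out) if out.ndim == 0 else out


def zeta(s, params: SwitchParams = SwitchParams()):
    """Decreasing signal transfer: ``gain * K2^2 / (K2^2 + s^2)``."""
    s = np.asarray(s, dtype=float)
    out = params.signal_gain * params.K2 ** 2 / (params.K2 ** 2 + s ** 2)
    return float(out) if out.ndim == 0 else out


def alpha_rates(lineage: int, s: SignalPair, params: SwitchParams = SwitchParams()):
    """Signal-modulated self-activation rates ``(alpha_x, alpha_y)``."""
    if lineage not in (1, 2):
        raise InvalidSpecError("lineage must be 1 or 2")
    e1, e2 = eta(s.s1, params), eta(s.s2, params)
    z1, z2 = zeta(s.s1, params), zeta(s.s2, params)
    if params.scaling == "product":
        # one gain per eta*zeta product instead of one per factor
        e1, z1 = e1 / params.signal_gain, z1 / params.signal_gain
    if lineage == 1:
        return (params.alpha0_x + e1 * e2, params.alpha0_y + z1 * z2)
    return (params.alpha0_x + e2 * z1, params.alpha0_y + e1 * z2)


def switch_rhs(state, alphas, params: SwitchParams = SwitchParams()):
    """Time derivatives (dx/dt, dy/dt) of the switch; accepts scalars or
    arrays for ``state = (x, y)``."""
    if isinstance(state, DeterminantState):
        x, y = state.x, state.y
    else:
        x, y = state
    ax, ay = alphas
    n, b = params.n, params.beta
    bn = b ** n
    xn = np.maximum(x, 0.0) ** n
    yn = np.maximum(y, 0.0) ** n
    dx = ax * xn / (bn + xn) + params.k1 * bn / (bn + yn) - params.gamma1 * x
    dy = ay * yn / (bn + yn) + params.k2 * bn / (bn + xn) - params.gamma2 * y
    return dx, dy


def _jacobian(x, y, alphas, p: SwitchParams):
    ax, ay = alphas
    n, bn = p.n, p.beta ** p.n
    xn, yn = x ** n, y ** n
    hx = n * bn * x ** (n - 1) / (bn + xn) ** 2 if x > 0 else 0.0
    hy = n * bn * y ** (n - 1) / (bn + yn) ** 2 if y > 0 else 0.0
    return np.array([
        [ax * hx - p.gamma1, -p.k1 * hy],
        [-p.k2 * hx, ay * hy - p.gamma2],
    ])


def find_attractors(
    alphas,
    params: SwitchParams = SwitchParams(),
    grid_n: int = 60,
) -> list[dict]:
    """Locate the linearly stable fixed points of the switch.

    A ``grid_n x grid_n`` scan over ``[0, (alpha+k)/gamma]^2`` seeds Newton
    refinement of the local minima of |rhs|^2; duplicates are merged and only
    roots whose Jacobian eigenvalues have negative real parts are kept,
    sorted by x.  Each entry is ``{"x", "y", "eigenvalues"}``.
    """
    ax, ay = alphas
    x_hi = (ax + params.k1) / params.gamma1 * 1.05
    y_hi = (ay + params.k2) / params.gamma2 * 1.05
    xs = np.linspace(0.0, x_hi, grid_n)
    ys = np.linspace(0.0, y_hi, grid_n)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    dX, dY = switch_rhs((X, Y), alphas, params)
    norm2 = dX ** 2 + dY ** 2
    # local minima of the residual norm on the grid
    m = np.ones_like(norm2, dtype=bool)
    m[1:, :] &= norm2[1:, :] <= norm2[:-1, :]
    m[:-1, :] &= norm2[:-1, :] <= norm2[1:, :]
    m[:, 1:] &= norm2[:, 1:] <= norm2[:, :-1]
    m[:, :-1] &= norm2[:, :-1] <= norm2[:, 1:]
    seeds = np.column_stack([X[m], Y[m]])

    def fun(z):
        dx, dy = switch_rhs((z[0], z[1]), alphas, params)
        return [dx, dy]

    found: list[tuple[float, float]] = []
    for seed in seeds:
        sol = root(fun, seed, method="hybr", tol=1e-12)
        if not sol.success:
            continue
        x0, y0 = sol.x
        if x0 < -1e-9 or y0 < -1e-9:
            continue
        x0, y0 = max(x0, 0.0), max(y0, 0.0)
        if any(abs(x0 - a) < 1e-4 * (1 + x_hi) and abs(y0 - b) < 1e-4 * (1 + y_hi)
               for a, b in found):
            continue
        found.append((x0, y0))

    out = []
    for x0, y0 in found:
        ev = np.linalg.eigvals(_jacobian(x0, y0, alphas, params))
        if np.all(ev.real < 0):
            out.append({"x": x0, "y": y0, "eigenvalues": ev})
    out.sort(key=lambda a: a["x"])
    return out


def stem_state(params: SwitchParams = SwitchParams()) -> tuple[float, float]:
    """Baseline stem attractor (the diagonal fixed point at zero bias).

    With ``alpha0 == k`` the diagonal point has the closed form
    ``x = y = alpha0/gamma1``; it is recomputed numerically from the
    parameters so perturbed parameter sets stay consistent.
    """
    alphas = (params.alpha0_x, params.alpha0_y)
    atts = find_attractors(alphas, params)
    if not atts:
        raise InvalidSpecError("no stable baseline attractor found")
    # the attractor closest to the diagonal is the stem state
    best = min(atts, key=lambda a: abs(a["x"] - a["y"]))
    return best["x"], best["y"]


def fate_from_point(
    x: float,
    y: float,
    lineage: int,
    rel_tol: float = 0.2,
) -> Fate:
    """Map a settled determinant pair to a fate.

    A point whose coordinates differ by less than ``rel_tol`` of their
    maximum is a self-renewing stem state; otherwise the larger determinant
    decides (high-x or high-y offspring).
    """
    stem, hi_x, hi_y = _LINEAGE_TRIPLE[lineage]
    top = max(x, y, 1e-12)
    if abs(x - y) <= rel_tol * top:
        return FATES[stem]
    return FATES[hi_x] if x > y else FATES[hi_y]


def _descend(x0, y0, alphas, params, t_max=80.0):
    """Deterministic descent to an attractor from (x0, y0)."""
    def rhs(_, z):
        dx, dy = switch_rhs((z[0], z[1]), alphas, params)
        return [dx, dy]

    sol = solve_ivp(rhs, (0.0, t_max), [x0, y0], method="LSODA",
                    rtol=1e-7, atol=1e-9)
    return float(sol.y[0, -1]), float(sol.y[1, -1])


def classify_fate(
    lineage: int,
    s: SignalPair,
    params: SwitchParams = SwitchParams(),
    mode: str = "deterministic",
    seed: int | None = None,
    omega_det: float = 1.0,
    t_cycle: float = 12.0,
) -> Fate:
    """Fate of a stem cell exposed to the signal pair (s1, s2).

    Deterministic mode integrates the switch from the stem initial state
    until it settles in an attractor basin.  Stochastic mode first runs a
    Gillespie realization of the determinant reactions (production with the
    Hill propensities, linear degradation) for one cycle span, then descends
    deterministically from the stochastic endpoint.
    """
    alphas = alpha_rates(lineage, s, params)
    x0, y0 = stem_state(params)
    if mode == "stochastic":
        x0, y0 = _ssa_determinants(x0, y0, alphas, params, omega_det,
                                   t_cycle, seed)
    elif mode != "deterministic":
        raise InvalidSpecError(f"unknown mode {mode!r}")
    xf, yf = _descend(x0, y0, alphas, params)
    return fate_from_point(xf, yf, lineage)


def _ssa_determinants(x0, y0, alphas, params, omega, t_cycle, seed):
    """Exact SSA for a single cell's four determinant reactions."""
    rng = np.random.default_rng(seed)
    ax, ay = alphas
    n, bn = params.n, params.beta ** params.n
    X = int(round(x0 * omega))
    Y = int(round(y0 * omega))
    t = 0.0
    while t < t_cycle:
        x, y = X / omega, Y / omega
        xn, yn = x ** n, y ** n
        a = np.array([
            omega * (ax * xn / (bn + xn) + params.k1 * bn / (bn + yn)),
            omega * params.gamma1 * x,
            omega * (ay * yn / (bn + yn) + params.k2 * bn / (bn + xn)),
            omega * params.gamma2 * y,
        ])
        a_tot = a.sum()
        if a_tot <= 0:
            break
        t += rng.exponential(1.0 / a_tot)
        if t >= t_cycle:
            break
        r = rng.random() * a_tot
        if r < a[0]:
            X += 1
        elif r < a[0] + a[1]:
            X -= 1
        elif r < a[0] + a[1] + a[2]:
            Y += 1
        else:
            Y -= 1
    return X / omega, Y / omega


def phase_field(
    lineage: int,
    params: SwitchParams = SwitchParams(),
    resolution: int = 21,
) -> np.ndarray:
    """Deterministic fate codes over the (s1, s2) plane.

    Returns a ``resolution x resolution`` integer matrix; entry ``[i, j]``
    is the fate code at ``s1 = 5 i/(res-1)``, ``s2 = 5 j/(res-1)``.
    """
    if resolution < 2:
        raise InvalidSpecError("resolution must be >= 2")
    svals = np.linspace(0.0, 5.0, resolution)
    out = np.empty((resolution, resolution), dtype=int)
    x0, y0 = stem_state(params)
    for i, s1 in enumerate(svals):
        for j, s2 in enumerate(svals):
            alphas = alpha_rates(lineage, SignalPair(s1, s2), params)
            xf, yf = _descend(x0, y0, alphas, params)
            out[i, j] = fate_from_point(xf, yf, lineage).code
    return out
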
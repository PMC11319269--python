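"""Stochastic simulation of the 20-reaction system.

Per signal channel i in {1, 2} (counts live on a lattice; Omega converts one
concentration unit to copies):

    production of s_u   gamma (A s_u + C) Omega     (off at the s_u cap)
    removal of s_u      gamma s_v Omega             (off at zero copies)
    production of s_v   gamma B s_u Omega
    removal of s_v      gamma (s_v + 1) Omega       (off at zero copies)
    s_u hop             1/h^2    per molecule per neighbor direction
    s_v hop             d/h^2    per molecule per neighbor direction

(diffusion in activator-scaled units: the activator hop rate is Du/h^2 with
Du rescaled to 1).  Per cell, the determinant reactions:

    production of x     alpha_x x^n/(beta^n+x^n) + k1 beta^n/(beta^n+y^n)
    degradation of x    gamma1 x
    production of y     alpha_y y^n/(beta^n+y^n) + k2 beta^n/(beta^n+x^n)
    degradation of y    gamma2 y

Reflective boundaries are realized as absent hop channels across the domain
edge.  The exact direct-method SSA serves small instances; tau-leaping with a
bounded relative-propensity-change criterion accelerates large ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ExtinctSystemError, InvalidGeometryError, InvalidSpecError
from .fate_switch import SwitchParams, alpha_rates, SignalPair
from .signal_fields import RDParams

__all__ = [
    "Reaction",
    "LatticeState",
    "build_reaction_table",
    "reaction_kinds",
    "gillespie_step",
    "simulate",
]

_TAU_EPSILON = 0.03  # bounded relative-change criterion for tau-leaping


@dataclass
class LatticeState:
    """Integer copy numbers per species per site, plus conversion factors.

    ``counts`` maps species names (``su1``, ``sv1``, ``su2``, ``sv2``, ``x``,
    ``y``) to 2-D integer arrays of a common shape.  ``omega`` converts
    signal concentrations to copies, ``omega_det`` determinant
    concentrations.  ``lineages`` (same shape, values 1/2) assigns each
    lattice cell a stem-cell type; ``fixed_alphas`` optionally pins the
    determinant self-activation rates when no signal species are present.
    """

    counts: dict[str, np.ndarray]
    omega: float = 100.0
    omega_det: float = 1.0
    t: float = 0.0
    lineages: np.ndarray | None = None
    fixed_alphas: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        shapes = {v.shape for v in self.counts.values()}
        if len(shapes) > 1:
            raise InvalidGeometryError("species arrays must share a shape")
        for k, v in self.counts.items():
            self.counts[k] = np.asarray(v, dtype=np.int64)
            if (self.counts[k] < 0).any():
                raise InvalidSpecError(f"negative copy number in {k}")

    @property
    def shape(self):
        return next(iter(self.counts.values())).shape

    def concentration(self, species: str) -> np.ndarray:
        om = self.omega_det if species in ("x", "y") else self.omega
        return self.counts[species] / om

    def copy(self) -> "LatticeState":
        return LatticeState(
            {k: v.copy() for k, v in self.counts.items()},
            self.omega, self.omega_det, self.t,
            None if self.lineages is None else self.lineages.copy(),
            self.fixed_alphas,
        )


@dataclass(frozen=True)
class Reaction:
    """One reaction channel of the Table-style system.

    ``table_row`` is the 1-10 row id, ``channel`` the signal channel (1/2)
    or, for determinant rows, the site's lineage.  ``site`` and (for
    diffusion) ``neighbor`` are lattice coordinates.  ``delta`` lists
    ``(species, site, +-1)`` stoichiometry entries.
    """

    table_row: int
    channel: int
    kind: str  # production | degradation | diffusion
    species: str
    site: tuple[int, int]
    neighbor: tuple[int, int] | None = None
    rd: RDParams | None = None
    sw: SwitchParams | None = None

    @property
    def delta(self):
        s, i = self.species, self.site
        if self.kind == "diffusion":
            return ((s, i, -1), (s, self.neighbor, +1))
        return ((s, i, +1 if self.kind == "production" else -1),)

    def propensity(self, state: LatticeState) -> float:
        r, c = self.site
        row = self.table_row
        if row in (1, 2, 4, 5):
            p = self.rd
            su = state.counts[f"su{self.channel}"][r, c] / state.omega
            sv = state.counts[f"sv{self.channel}"][r, c] / state.omega
            if row == 1:  # s_u production, nullified at the confinement cap
                cap = int(round(p.su_max * state.omega))
                if state.counts[f"su{self.channel}"][r, c] >= cap:
                    return 0.0
                return p.gamma * (p.A * su + p.C) * state.omega
            if row == 2:  # s_u removal at rate gamma*s_v
                if state.counts[f"su{self.channel}"][r, c] == 0:
                    return 0.0
                return p.gamma * sv * state.omega
            if row == 4:  # s_v production at rate gamma*B*s_u
                return p.gamma * p.B * su * state.omega
            # row 5: s_v removal at rate gamma*(s_v + 1)
            if state.counts[f"sv{self.channel}"][r, c] == 0:
                return 0.0
            return p.gamma * (sv + 1.0) * state.omega
        if row in (3, 6):
            p = self.rd
            d_eff = 1.0 if row == 3 else p.d
            n = state.counts[self.species][r, c]
            return n * d_eff / (p.h * p.h)
        # determinant rows 7-10
        sw = self.sw
        x = state.counts["x"][r, c] / state.omega_det
        y = state.counts["y"][r, c] / state.omega_det
        if row == 8:
            return sw.gamma1 * x * state.omega_det
        if row == 10:
            return sw.gamma2 * y * state.omega_det
        ax, ay = self._alphas(state, r, c)
        bn = sw.beta ** sw.n
        if row == 7:
            hill = x ** sw.n
            return (ax * hill / (bn + hill) + sw.k1 * bn / (bn + y ** sw.n)) \
                * state.omega_det
        hill = y ** sw.n
        return (ay * hill / (bn + hill) + sw.k2 * bn / (bn + x ** sw.n)) \
            * state.omega_det

    def _alphas(self, state, r, c):
        if state.fixed_alphas is not None:
            return state.fixed_alphas[0][r, c], state.fixed_alphas[1][r, c]
        if "su1" in state.counts and "su2" in state.counts:
            s1 = min(state.counts["su1"][r, c] / state.omega
                     / self.rd.su_max * 5.0, 5.0) if self.rd else 0.0
            s2 = min(state.counts["su2"][r, c] / state.omega
                     / self.rd.su_max * 5.0, 5.0) if self.rd else 0.0
            return alpha_rates(self.channel, SignalPair(s1, s2), self.sw)
        return self.sw.alpha0_x, self.sw.alpha0_y

    def apply(self, state: LatticeState) -> None:
        for species, site, change in self.delta:
            arr = state.counts[species]
            arr[site] += change
            if arr[site] < 0:  # guard; propensity rules should prevent this
                arr[site] = 0


def _neighbors(r, c, nr, nc):
    if r > 0:
        yield r - 1, c
    if r < nr - 1:
        yield r + 1, c
    if c > 0:
        yield r, c - 1
    if c < nc - 1:
        yield r, c + 1


def build_reaction_table(
    rd: tuple[RDParams, RDParams] | None,
    sw: SwitchParams | None,
    geometry,
    lineages: np.ndarray | None = None,
) -> list[Reaction]:
    """Instantiate every reaction channel on a rectangular lattice.

    ``geometry`` is an int (square side) or a ``(rows, cols)`` pair.  ``rd``
    supplies the two signal channels (pass ``None`` to omit signal
    reactions); ``sw`` the determinant reactions (``None`` to omit).
    Exactly 10 reaction kinds per channel / cell type are emitted.
    """
    if isinstance(geometry, int):
        nr = nc = geometry
    else:
        try:
            nr, nc = geometry
        except (TypeError, ValueError):
            raise InvalidGeometryError(f"bad geometry {geometry!r}") from None
    if nr < 1 or nc < 1:
        raise InvalidGeometryError("lattice must have at least one site")

    out: list[Reaction] = []
    if rd is not None:
        for ch, p in zip((1, 2), rd):
            for r in range(nr):
                for c in range(nc):
                    site = (r, c)
                    out.append(Reaction(1, ch, "production", f"su{ch}", site, rd=p))
                    out.append(Reaction(2, ch, "degradation", f"su{ch}", site, rd=p))
                    out.append(Reaction(4, ch, "production", f"sv{ch}", site, rd=p))
                    out.append(Reaction(5, ch, "degradation", f"sv{ch}", site, rd=p))
                    for nb in _neighbors(r, c, nr, nc):
                        out.append(Reaction(3, ch, "diffusion", f"su{ch}",
                                            site, neighbor=nb, rd=p))
                        out.append(Reaction(6, ch, "diffusion", f"sv{ch}",
                                            site, neighbor=nb, rd=p))
    if sw is not None:
        rd1 = rd[0] if rd is not None else None
        for r in range(nr):
            for c in range(nc):
                lin = int(lineages[r, c]) if lineages is not None else 1
                site = (r, c)
                out.append(Reaction(7, lin, "production", "x", site, rd=rd1, sw=sw))
                out.append(Reaction(8, lin, "degradation", "x", site, rd=rd1, sw=sw))
                out.append(Reaction(9, lin, "production", "y", site, rd=rd1, sw=sw))
                out.append(Reaction(10, lin, "degradation", "y", site, rd=rd1, sw=sw))
    return out


def reaction_kinds(reactions: list[Reaction]) -> set[tuple[int, int]]:
    """Distinct (table_row, channel) kinds present in a reaction list."""
    return {(rx.table_row, rx.channel) for rx in reactions}


@dataclass
class EventRecord:
    waiting_time: float
    reaction: Reaction
    state: LatticeState


def gillespie_step(state: LatticeState, reactions: list[Reaction], rng) -> EventRecord:
    """One exact direct-method event: exponential waiting time at the total
    propensity, channel chosen proportionally, stoichiometry applied."""
    a = np.fromiter((rx.propensity(state) for rx in reactions),
                    dtype=float, count=len(reactions))
    a_tot = a.sum()
    if a_tot <= 0.0:
        raise ExtinctSystemError("all propensities are zero")
    tau = rng.exponential(1.0 / a_tot)
    j = int(np.searchsorted(np.cumsum(a), rng.random() * a_tot))
    j = min(j, len(reactions) - 1)
    reactions[j].apply(state)
    state.t += tau
    return EventRecord(tau, reactions[j], state)


def _tau_leap_once(state, reactions, a, rng, horizon):
    """One accepted tau-leap; returns the time advanced (0 on rejection)."""
    a_tot = a.sum()
    # bounded relative change: limit expected relative drift per species
    mu: dict[tuple[str, tuple], float] = {}
    for rx, aj in zip(reactions, a):
        if aj == 0.0:
            continue
        for species, site, change in rx.delta:
            mu[(species, site)] = mu.get((species, site), 0.0) + change * aj
    tau = horizon - state.t
    for (species, site), drift in mu.items():
        if drift == 0.0:
            continue
        x = max(float(state.counts[species][site]), 1.0)
        tau = min(tau, _TAU_EPSILON * x / abs(drift))
    if tau * a_tot < 10.0:  # leap not worthwhile; caller falls back to SSA
        return -1.0
    fires = rng.poisson(a * tau)
    # reject leaps that would drive any count negative
    trial = {k: v.copy() for k, v in state.counts.items()}
    ok = True
    for rx, k in zip(reactions, fires):
        if k == 0:
            continue
        for species, site, change in rx.delta:
            trial[species][site] += change * k
            if trial[species][site] < 0:
                ok = False
                break
        if not ok:
            break
    if not ok:
        return 0.0
    for k, v in trial.items():
        state.counts[k] = v
    state.t += tau
    return tau


def simulate(
    state: LatticeState,
    reactions: list[Reaction],
    horizon: float,
    method: str = "ssa",
    seed: int | None = None,
    snapshot_every: float | None = None,
    max_events: int | None = None,
) -> list[LatticeState]:
    """Advance the system to ``t = horizon``; returns snapshots (always
    including the final state).  Reproducible given ``seed``.  Tau-leaping
    falls back to exact SSA whenever a leap is rejected or too small."""
    if horizon <= 0:
        raise InvalidSpecError("horizon must be positive")
    if method not in ("ssa", "tau_leap"):
        raise InvalidSpecError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    snaps: list[LatticeState] = []
    next_snap = snapshot_every if snapshot_every else np.inf
    events = 0
    while state.t < horizon:
        if max_events is not None and events >= max_events:
            break
        if method == "ssa":
            gillespie_step(state, reactions, rng)
            events += 1
        else:
            a = np.fromiter((rx.propensity(state) for rx in reactions),
                            dtype=float, count=len(reactions))
            if a.sum() <= 0.0:
                raise ExtinctSystemError("all propensities are zero")
            adv = _tau_leap_once(state, reactions, a, rng, horizon)
            events += 1
            if adv < 0.0:  # leap-failure: take a burst of exact steps
                for _ in range(20):
                    if state.t >= horizon:
                        break
                    try:
                        gillespie_step(state, reactions, rng)
                    except ExtinctSystemError:
                        break
        while state.t >= next_snap:
            snaps.append(state.copy())
            next_snap += snapshot_every
    snaps.append(state.copy())
    return snaps
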
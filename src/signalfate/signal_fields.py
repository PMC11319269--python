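"""Deterministic signal layers: static positional-information profiles and the
confined Turing reaction-diffusion dynamic.

Two independent activator/inhibitor pairs ``(s_u, s_v)`` evolve by

    ds_u/dt = lap(s_u)     + gamma * f(s_u, s_v),   f = A*s_u - s_v + C
    ds_v/dt = d * lap(s_v) + gamma * g(s_u, s_v),   g = B*s_u - s_v - 1

with reflective boundaries and the confinement ``0 <= s_u <= su_max``.  The
signal a cell reads is the activator field ``s_u``.  Space is measured in
activator-diffusion units, so the effective diffusivities are ``(1, d)`` with
``d = Dv/Du``; the printed ``Du``/``Dv`` of a parameter set only fix ``d``.

The family of confined steady states has three members -- spots, reverse spots
and stripes -- selected by the activator cap ``su_max`` (and the diffusivity
ratio).  :func:`classify_pattern` assigns one of these labels to a steady
field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import (
    CFLViolationError,
    DegenerateKineticsError,
    InvalidSpecError,
)

__all__ = [
    "RDParams",
    "SignalField",
    "StaticProfileSpec",
    "RD_PRESETS",
    "homogeneous_steady_state",
    "turing_unstable",
    "integrate_rd",
    "static_profile",
    "normalize_to_scale",
    "classify_pattern",
]


@dataclass(frozen=True)
class RDParams:
    """Reaction-diffusion constants for one signal channel.

    Parameters
    ----------
    A, B, C : float
        Linear kinetic coefficients of ``f = A*su - sv + C`` and
        ``g = B*su - sv - 1``.
    gamma : float
        Relative strength of the reaction kinetics.
    Du, Dv : float
        Diffusivities of activator and inhibitor.  Only the ratio
        ``d = Dv/Du`` enters the rescaled dynamic.
    h : float
        Lattice spacing of the spatial discretization.
    su_max : float
        Upper confinement bound on the activator; the control parameter
        selecting spot / reverse-spot / stripe steady states.
    """

    A: float = 0.9
    B: float = 1.2
    C: float = 0.2
    gamma: float = 10_000.0
    Du: float = 1.0
    Dv: float = 20.0
    h: float = 0.01
    su_max: float = 5.0

    def __post_init__(self):
        for name in ("A", "B", "C", "gamma", "Du", "Dv", "h", "su_max"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"RDParams.{name} must be >= 0")
        if self.su_max <= 0:
            raise InvalidSpecError("su_max must be positive")
        if self.h <= 0:
            raise InvalidSpecError("h must be positive")

    @property
    def d(self) -> float:
        """Diffusivity ratio Dv/Du (inf if Du == 0 and Dv > 0)."""
        if self.Du > 0:
            return self.Dv / self.Du
        return 0.0 if self.Dv == 0 else float("inf")


@dataclass
class SignalField:
    """A square, non-negative concentration grid for one signal channel."""

    values: np.ndarray
    scale_max: float = 5.0
    channel_id: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InvalidSpecError("SignalField values must be a square matrix")
        if self.values.shape[0] < 2:
            raise InvalidSpecError("SignalField needs sz >= 2")

    @property
    def sz(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "SignalField":
        return SignalField(self.values.copy(), self.scale_max, self.channel_id)


@dataclass(frozen=True)
class StaticProfileSpec:
    """Static positional-information profile: Gaussian bump or sinusoid.

    ``kind='gaussian'`` evaluates ``exp(-((x-x*)^2+(y-y*)^2) / (2 sigma^2))``;
    ``kind='sinusoidal'`` evaluates ``sin(k*x)`` (constant along y).  Grid
    coordinates are 0-based (row, column) with row = y.
    """

    kind: str
    x_star: float = 0.0
    y_star: float = 0.0
    sigma: float = 1.0
    k: float = 1.0

    def __post_init__(self):
        if self.kind not in ("gaussian", "sinusoidal"):
            raise InvalidSpecError(f"unknown profile kind {self.kind!r}")
        if self.kind == "gaussian" and not self.sigma > 0:
            raise InvalidSpecError("gaussian profile needs sigma > 0")
        if self.kind == "sinusoidal" and self.k == 0:
            raise InvalidSpecError("sinusoidal profile needs k != 0")


def homogeneous_steady_state(params: RDParams) -> tuple[float, float]:
    """Unique root of f = g = 0: ``su* = (C+1)/(B-A)``, ``sv* = B su* - 1``.

    Both components are returned even if negative; admissibility is the
    caller's concern.  Raises :class:`DegenerateKineticsError` when B == A.
    """
    if params.B == params.A:
        raise DegenerateKineticsError("B == A leaves no unique kinetics root")
    su = (params.C + 1.0) / (params.B - params.A)
    sv = params.B * su - 1.0
    return su, sv


def turing_unstable(params: RDParams) -> tuple[bool, tuple[float, float] | None]:
    """Linear dispersion analysis about the homogeneous steady state.

    The reaction Jacobian is ``gamma * [[A, -1], [B, -1]]``.  A wavenumber
    band ``q^2 in (q2_lo, q2_hi)`` grows iff the determinant polynomial

        h(q^2) = d q^4 - gamma (d A - 1) q^2 + gamma^2 (B - A)

    dips negative, which requires ``d A > 1`` and
    ``(d A - 1)^2 > 4 d (B - A)``.  Returns ``(flag, interval)`` with
    ``interval=None`` when stable.
    """
    homogeneous_steady_state(params)  # raises if degenerate
    A, B, g, d = params.A, params.B, params.gamma, params.d
    if d == 0:  # diffusionless: no diffusion-driven instability
        return False, None
    b = g * (d * A - 1.0)
    det0 = g * g * (B - A)
    if b <= 0:
        return False, None
    disc = b * b - 4.0 * d * det0
    if disc <= 0:
        return False, None
    root = np.sqrt(disc)
    q2_lo = (b - root) / (2.0 * d)
    q2_hi = (b + root) / (2.0 * d)
    return q2_hi > 0, (max(q2_lo, 0.0), q2_hi)


def _laplacian(u: np.ndarray, h: float) -> np.ndarray:
    """5-point Laplacian with zero-flux (reflective) boundaries."""
    p = np.pad(u, 1, mode="edge")
    return (
        p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * u
    ) / (h * h)


def integrate_rd(
    params: RDParams,
    init: tuple[SignalField, SignalField] | None = None,
    t_end: float = 0.01,
    seed: int | None = None,
    sz: int = 100,
    noise_amplitude: float = 0.01,
    dt: float | None = None,
    channel_id: int = 1,
) -> tuple[SignalField, SignalField]:
    """Explicit-Euler integration of the confined dynamic to time ``t_end``.

    Without ``init`` the fields start at the homogeneous steady state with
    multiplicative uniform noise of relative amplitude ``noise_amplitude``
    (seeded).  The activator is clamped into ``[0, su_max]`` after every step.
    A user-supplied ``dt`` above the diffusion stability bound raises
    :class:`CFLViolationError`.
    """
    if t_end <= 0:
        raise InvalidSpecError("t_end must be positive")
    d_eff = params.d
    diff_u = 1.0 if params.Du > 0 else 0.0
    diff_v = d_eff if np.isfinite(d_eff) else 0.0
    if params.Du == 0 and params.Dv > 0:
        raise InvalidSpecError("Dv > 0 with Du == 0 is not representable")

    max_diff = max(diff_u, diff_v)
    cfl = 0.25 * params.h ** 2 / max_diff if max_diff > 0 else np.inf
    # reaction stability: |eigenvalues| of gamma*J are O(gamma * (1+A+B))
    react = 0.5 / (params.gamma * (1.0 + params.A + params.B)) if params.gamma > 0 else np.inf
    if dt is None:
        dt = min(0.8 * cfl, react)
    elif dt > cfl:
        raise CFLViolationError(
            f"dt={dt:g} exceeds diffusion stability bound {cfl:g}"
        )

    if init is not None:
        su = np.array(init[0].values, dtype=float)
        sv = np.array(init[1].values, dtype=float)
        if su.shape != sv.shape:
            raise InvalidSpecError("init fields must share a shape")
    else:
        su0, sv0 = homogeneous_steady_state(params)
        rng = np.random.default_rng(seed)
        su = np.full((sz, sz), su0)
        sv = np.full((sz, sz), sv0)
        if noise_amplitude > 0:
            su *= 1.0 + noise_amplitude * rng.uniform(-1.0, 1.0, (sz, sz))
            sv *= 1.0 + noise_amplitude * rng.uniform(-1.0, 1.0, (sz, sz))

    np.clip(su, 0.0, params.su_max, out=su)
    np.maximum(sv, 0.0, out=sv)

    A, B, C, g, h = params.A, params.B, params.C, params.gamma, params.h
    n_steps = int(np.ceil(t_end / dt))
    dt = t_end / n_steps
    for _ in range(n_steps):
        f = A * su - sv + C
        gk = B * su - sv - 1.0
        su_new = su + dt * (diff_u * _laplacian(su, h) + g * f)
        sv_new = sv + dt * (diff_v * _laplacian(sv, h) + g * gk)
        np.clip(su_new, 0.0, params.su_max, out=su_new)
        np.maximum(sv_new, 0.0, out=sv_new)
        su, sv = su_new, sv_new

    return (
        SignalField(su, scale_max=params.su_max, channel_id=channel_id),
        SignalField(sv, scale_max=params.su_max, channel_id=channel_id),
    )


def static_profile(spec: StaticProfileSpec, sz: int) -> SignalField:
    """Evaluate a static profile on the integer grid (row = y, column = x)."""
    if sz < 2:
        raise InvalidSpecError("sz must be >= 2")
    y, x = np.mgrid[0:sz, 0:sz].astype(float)
    if spec.kind == "gaussian":
        r2 = (x - spec.x_star) ** 2 + (y - spec.y_star) ** 2
        vals = np.exp(-r2 / (2.0 * spec.sigma ** 2))
    else:
        vals = np.sin(spec.k * x)
    return SignalField(vals, scale_max=5.0)


def normalize_to_scale(f: SignalField, scale_max: float = 5.0) -> SignalField:
    """Affine map of [min, max] onto [0, scale_max]; constant fields map to
    the midpoint ``scale_max / 2``."""
    v = f.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        out = np.full_like(v, scale_max / 2.0)
    else:
        out = (v - lo) * (scale_max / (hi - lo))
    return SignalField(out, scale_max=scale_max, channel_id=f.channel_id)


# -- pattern classification ---------------------------------------------------

_FOUR = ndimage.generate_binary_structure(2, 1)


def _phase_stats(mask: np.ndarray) -> dict:
    """Connected-component statistics of one binary phase."""
    labels, n = ndimage.label(mask, structure=_FOUR)
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    elong = []
    spanning = 0
    sz = mask.shape[0]
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labels == comp)
        if rows.size < 2:
            elong.append(1.0)
            continue
        if rows.max() - rows.min() == sz - 1 or cols.max() - cols.min() == sz - 1:
            spanning += 1
        pts = np.column_stack([rows, cols]).astype(float)
        cov = np.cov(pts.T)
        ev = np.sort(np.abs(np.linalg.eigvalsh(cov)))
        elong.append(np.sqrt(ev[1] / max(ev[0], 0.25)))
    areas = np.asarray(areas, dtype=float)
    elong = np.asarray(elong, dtype=float)
    w = areas / areas.sum() if areas.size else areas
    return {
        "n": n,
        "areas": areas,
        "max_area_frac": float(areas.max() / areas.sum()) if n else 0.0,
        "mean_elong": float((w * elong).sum()) if n else 0.0,
        "spanning": spanning,
    }


def classify_pattern(
    f: SignalField,
    rel_amplitude_tol: float = 0.02,
    missing: np.ndarray | None = None,
) -> str:
    """Label a steady field as ``spot``, ``reverse_spot``, ``stripe`` or
    ``none``.

    The field is binarized at its mean; the two phases are analyzed by
    connected components.  Many compact above-mean islands over one dominant
    below-mean background mean *spot*; the complement means *reverse spot*;
    elongated interleaved phases mean *stripe*; negligible relative amplitude
    (below ``rel_amplitude_tol`` of the scale) means *none*.  ``missing``
    masks pixels carrying no information (used by the inverse route).
    """
    v = np.asarray(f.values, dtype=float)
    valid = np.isfinite(v)
    if missing is not None:
        valid &= ~missing
    vv = v[valid]
    if vv.size == 0:
        return "none"
    amp = float(vv.max() - vv.min())
    scale = max(f.scale_max, abs(float(vv.max())), 1e-12)
    if amp < rel_amplitude_tol * scale:
        return "none"
    thr = float(vv.mean())
    hi = (v > thr) & valid
    lo = (v < thr) & valid
    # pixels exactly at the mean join the phase that keeps hi/lo complementary
    eq = (v == thr) & valid
    if eq.any():
        hi |= eq
    s_hi, s_lo = _phase_stats(hi), _phase_stats(lo)
    if s_hi["n"] == 0 or s_lo["n"] == 0:
        return "none"

    # the minority phase carries the shape information: compact islands in
    # a connected background belong to the spot family (high islands: spot,
    # low holes: reverse spot); elongated or domain-spanning minority
    # structures mean interleaved bands (stripe / labyrinth)
    hi_area = float(s_hi["areas"].sum())
    lo_area = float(s_lo["areas"].sum())
    minority, majority, minority_is_hi = (
        (s_hi, s_lo, True) if hi_area <= lo_area else (s_lo, s_hi, False))
    ELONG = 2.1  # island vs trough elongation cut (area-weighted PCA ratio)

    if (minority["n"] >= 3 and minority["spanning"] == 0
            and majority["max_area_frac"] >= 0.75):
        if minority["mean_elong"] < ELONG:
            return "spot" if minority_is_hi else "reverse_spot"
        return "stripe"
    if minority["spanning"] >= 1 or minority["mean_elong"] >= 2.0 \
            or majority["max_area_frac"] < 0.75:
        return "stripe"
    return "spot" if minority_is_hi else "reverse_spot"


# -- presets ------------------------------------------------------------------

#: Named parameter sets behind the three confined-Turing steady-state classes.
#: Reaction constants are the printed ones (A=0.9, B=1.2, C=0.2, gamma=1e4,
#: h=0.01); the activator caps were calibrated by a one-dimensional scan over
#: su_max (see docs/methods.md).  The reverse-spot cap is pinned at 5 so its
#: steady field spans the (0, 5) decision scale.
RD_PRESETS: dict[str, RDParams] = {
    "spot": RDParams(Du=1.0, Dv=20.0, su_max=30.0),
    "reverse_spot": RDParams(Du=25.0, Dv=12_500.0, su_max=5.0),
    "stripe": RDParams(Du=1.0, Dv=20.0, su_max=6.0),
}


def preset(name: str) -> RDParams:
    """Look up a named reaction-diffusion preset."""
    try:
        return replace(RD_PRESETS[name])
    except KeyError:
        raise InvalidSpecError(f"unknown RD preset {name!r}") from None


#: the one-dimensional su_max scan (per diffusivity ratio) that located the
#: three steady-state classes; see docs/methods.md.
SU_MAX_SCAN: tuple[tuple[float, float], ...] = (
    (20.0, 4.5), (20.0, 6.0), (20.0, 30.0), (500.0, 5.0),
)


def pattern_family_scan(
    entries: tuple[tuple[float, float], ...] = SU_MAX_SCAN,
    sz: int = 100,
    t_end: float = 0.03,
    seed: int = 0,
) -> dict[tuple[float, float], str]:
    """Integrate the confined dynamic for each ``(d, su_max)`` entry at the
    study's reaction constants and classify the steady field."""
    out = {}
    for d, su_max in entries:
        p = RDParams(Du=1.0, Dv=float(d), su_max=float(su_max))
        su, _ = integrate_rd(p, t_end=t_end, seed=seed, sz=sz)
        out[(d, su_max)] = classify_pattern(su)
    return out
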
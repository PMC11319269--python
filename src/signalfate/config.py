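"""Run configuration: every tunable of the pipeline in one serializable
object.  Defaults are the study's printed values (reaction constants of the
confined Turing dynamic, switch rates, sz=100, epsilon=0.0025)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidSpecError, MalformedFileError
from .fate_switch import SwitchParams
from .signal_fields import RDParams, RD_PRESETS

__all__ = ["SignalSpec", "RunConfig"]


@dataclass(frozen=True)
class SignalSpec:
    """Where one signal plane comes from.

    kind:
      * ``preset`` -- steady state of a named confined-Turing preset
        (``name`` in {spot, reverse_spot, stripe}), normalized to (0, 5);
      * ``static`` -- a positional-information profile (``profile`` in
        {gaussian, sinusoidal} with its geometry), normalized to (0, 5);
      * ``csv`` -- a numeric matrix from ``path`` (``normalize`` controls
        rescaling to (0, 5));
      * ``uniform`` -- a spatially constant plane at ``value`` (no
        rescaling; used for frozen-signal experiments).
    """

    kind: str = "preset"
    name: str = "reverse_spot"
    profile: str = "gaussian"
    x_star: float = 40.0
    y_star: float = 30.0
    sigma: float = 2.0
    k: float = 4.5
    path: str = ""
    normalize: bool = True
    value: float = 2.5

    def __post_init__(self):
        if self.kind not in ("preset", "static", "csv", "uniform"):
            raise InvalidSpecError(f"unknown signal kind {self.kind!r}")
        if self.kind == "preset" and self.name not in RD_PRESETS:
            raise InvalidSpecError(f"unknown preset {self.name!r}")


@dataclass
class RunConfig:
    """Full configuration of a population run."""

    sz: int = 100
    fraction_sc1: float = 0.5
    signal1: SignalSpec = field(default_factory=lambda: SignalSpec())
    signal2: SignalSpec = field(default_factory=lambda: SignalSpec())
    rd1: RDParams = field(default_factory=RDParams)
    rd2: RDParams = field(default_factory=RDParams)
    switch: SwitchParams = field(default_factory=SwitchParams)
    omega: float = 100.0       # copies per signal concentration unit
    omega_det: float = 1.0     # copies per determinant concentration unit
    epsilon: float = 0.0025    # convergence threshold on max |pb_new - pb_old|
    cycle_steps: int = 100     # steps per cell cycle
    dt_step: float = 0.12      # simulated time per step (cycle span = 12)
    eval_every_steps: int = 1000   # probability evaluation cadence, in steps
    max_cycles: int = 20000    # iteration cap before NonConvergenceError
    leap_dt: float = 0.05      # tau-leap step of the determinant kernel
    t_descend: float = 60.0    # deterministic descent horizon
    fate_rel_tol: float = 0.2  # stem band of the settled-point classifier
    paint_mode: str = "argmax"      # or "sample"
    paint_scope: str = "lineage"    # or "population"
    offspring_only: bool = False    # restrict painting to differentiated fates
    signal_mode: str = "frozen"     # or "coevolve"
    signal_t_end: float = 0.03      # PDE horizon for preset signal generation
    signal_sz: int | None = None    # grid for signal generation (default sz)
    coevolve_dt: float = 1e-6       # tau-leap step of the signal kernel
    coevolve_time_per_cycle: float = 1e-4

    def __post_init__(self):
        if not 0.0 <= self.fraction_sc1 <= 1.0:
            raise InvalidSpecError("fraction_sc1 must lie in [0, 1]")
        if self.sz < 2:
            raise InvalidSpecError("sz must be >= 2")
        if self.paint_mode not in ("argmax", "sample"):
            raise InvalidSpecError(f"unknown paint_mode {self.paint_mode!r}")
        if self.paint_scope not in ("lineage", "population"):
            raise InvalidSpecError(f"unknown paint_scope {self.paint_scope!r}")
        if self.signal_mode not in ("frozen", "coevolve"):
            raise InvalidSpecError(f"unknown signal_mode {self.signal_mode!r}")
        if self.epsilon <= 0:
            raise InvalidSpecError("epsilon must be positive")

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        try:
            d = dict(data)
            for key, sub in (
                ("signal1", SignalSpec), ("signal2", SignalSpec),
                ("rd1", RDParams), ("rd2", RDParams), ("switch", SwitchParams),
            ):
                if key in d and isinstance(d[key], dict):
                    d[key] = sub(**d[key])
            return cls(**d)
        except (TypeError, InvalidSpecError) as exc:
            raise MalformedFileError(f"bad config: {exc}") from exc

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise MalformedFileError(f"unparseable config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise MalformedFileError(f"config {path} is not a mapping")
        return cls.from_dict(data)
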
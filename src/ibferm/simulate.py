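"""Synthetic biphasic batch-fermentation generator.

Emulates the phenomenology of clostridial IB fermentations so the analysis
pipeline can be exercised end-to-end without external data: an early
acidogenic phase accumulating acetic and butyric acid with a falling pH,
then a solventogenic phase in which acids are re-assimilated into butanol
while butanol, isopropanol and a transient pool of acetone are formed, the
acetone being converted first-order to isopropanol. Glucose–glycerol
mixtures are co-consumed with a configurable glycerol share of the
instantaneous substrate draw.

The kinetic form is deliberately simple — logistic biomass growth,
biomass-proportional substrate uptake, constant per-phase mass yields,
first-order conversions — integrated with an explicit Euler scheme. It is a
data generator with the right qualitative structure, not a mechanistic
model of the organism; preset parameters are calibrated to endpoint tables
only.

Measurement noise is added only to the emitted "measured" copy of the
trajectories; the latent truth is deterministic and independent of the
noise settings. Identical seeds give identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import ComputationError, ValidationError
from .io import EndpointRecord, TimeCourse, write_timecourse
from .registry import default_registry

__all__ = [
    "SimConfig",
    "simulate_batch",
    "endpoint_from_timecourse",
    "scenario",
    "scenario_names",
    "save_simulation",
]

logger = logging.getLogger(__name__)

#: mass gain of the acetone → isopropanol reduction (molar equivalence).
_ACT_TO_IPA = 60.10 / 58.08


@dataclass
class SimConfig:
    """Parameters of the synthetic biphasic batch model.

    Attributes
    ----------
    initial_substrates : dict
        Initial substrate loading, g/L (e.g. ``{"glucose": 21.85}``).
    inoculum_dcw : float
        Starting biomass, g DCW/L.
    mu_max : float
        Maximum specific growth rate of the logistic biomass model, 1/h.
    biomass_capacity : float
        Carrying capacity of the logistic model, g DCW/L.
    switch_time_h : float
        Time at which solventogenesis begins, h.
    acid_yields, solvent_yields : dict
        Mass yields (g product per g substrate drawn) applied during the
        acidogenic and solventogenic phase respectively; each phase's
        yields must sum to <= 1.
    acid_reassimilation_rate : float
        First-order rate (1/h) at which acids are taken back up during
        solventogenesis and converted to butanol.
    reassimilation_yield : float
        g butanol formed per g acid re-assimilated (default 1, mass
        conserving by construction).
    acetone_conversion_rate : float
        First-order acetone → isopropanol rate, 1/h (molar equivalence).
    glycerol_preference : float
        Fraction of the instantaneous substrate draw taken from glycerol
        while glycerol remains, in [0, 1].
    substrate_uptake_rate : float
        g substrate per g DCW per h.
    noise_sd : float
        Gaussian measurement noise (g/L) on the emitted copy, truncated
        at 0.
    seed : int
        RNG seed for the measurement noise.
    dt, t_end : float
        Euler step and horizon, h.
    """

    initial_substrates: dict[str, float]
    inoculum_dcw: float = 0.1
    mu_max: float = 0.4
    biomass_capacity: float = 3.0
    switch_time_h: float = 10.0
    acid_yields: dict[str, float] = field(
        default_factory=lambda: {"acetic_acid": 0.10, "butyric_acid": 0.25}
    )
    solvent_yields: dict[str, float] = field(
        default_factory=lambda: {"butanol": 0.16, "isopropanol": 0.10, "acetone": 0.03}
    )
    acid_reassimilation_rate: float = 0.06
    reassimilation_yield: float = 1.0
    acetone_conversion_rate: float = 0.05
    glycerol_preference: float = 0.0
    substrate_uptake_rate: float = 0.45
    noise_sd: float = 0.0
    seed: int = 0
    dt: float = 0.02
    t_end: float = 28.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        reg = default_registry()
        if not self.initial_substrates:
            raise ValidationError("initial_substrates must not be empty")
        for sp_id, conc in self.initial_substrates.items():
            if not reg.get(sp_id).is_substrate:
                raise ValidationError(f"{sp_id!r} is not a substrate")
            if conc < 0:
                raise ValidationError(f"negative initial {sp_id}: {conc}")
        for name in (
            "inoculum_dcw", "mu_max", "biomass_capacity",
            "acid_reassimilation_rate", "reassimilation_yield",
            "acetone_conversion_rate", "substrate_uptake_rate", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for attr in ("acid_yields", "solvent_yields"):
            yields = getattr(self, attr)
            if any(v < 0 for v in yields.values()):
                raise ValidationError(f"{attr} must be >= 0")
            if sum(yields.values()) > 1.0 + 1e-12:
                raise ValidationError(f"{attr} sum to more than 1 g/g")
        for sp_id in self.acid_yields:
            reg.get(sp_id)
        for sp_id in self.solvent_yields:
            reg.get(sp_id)
        if not 0.0 <= self.glycerol_preference <= 1.0:
            raise ValidationError("glycerol_preference must be in [0, 1]")
        if self.dt <= 0:
            raise ValidationError("dt must be > 0")
        if self.t_end <= 0:
            raise ValidationError("t_end must be > 0")
        if not self.switch_time_h < self.t_end:
            raise ValidationError("switch_time_h must be < t_end")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load from JSON or YAML (by extension)."""
        text = Path(path).read_text()
        if str(path).lower().endswith((".yaml", ".yml")):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: expected a mapping of SimConfig fields")
        return cls.from_dict(data)


def simulate_batch(config: SimConfig, latent: bool = False) -> TimeCourse:
    """Integrate the biphasic batch model and return the sampled time course.

    Explicit Euler at ``config.dt``. Returns the measured copy (latent plus
    truncated Gaussian noise) unless ``latent=True``; the latent trajectory
    never depends on ``noise_sd`` or ``seed``.
    """
    config.validate()
    n_steps = int(round(config.t_end / config.dt))
    times = np.arange(n_steps + 1) * config.dt

    sub_ids = list(config.initial_substrates)
    product_ids = list(dict.fromkeys(
        ["butanol", "isopropanol", "acetone", "acetic_acid", "butyric_acid",
         *config.acid_yields, *config.solvent_yields]
    ))
    subs = {sp: float(c) for sp, c in config.initial_substrates.items()}
    prods = {sp: 0.0 for sp in product_ids}
    X = float(config.inoculum_dcw)

    traj = {sp: np.empty(n_steps + 1) for sp in (*sub_ids, *product_ids)}
    biomass = np.empty(n_steps + 1)
    floor_events = {sp: 0 for sp in sub_ids}

    def record(i: int) -> None:
        for sp in sub_ids:
            traj[sp][i] = subs[sp]
        for sp in product_ids:
            traj[sp][i] = prods[sp]
        biomass[i] = X

    record(0)
    for i in range(n_steps):
        t = times[i]
        demand = config.substrate_uptake_rate * X * config.dt
        draws = _split_draw(demand, subs, config.glycerol_preference, floor_events)
        draw_total = sum(draws.values())
        for sp, d in draws.items():
            subs[sp] = max(0.0, subs[sp] - d)

        if t < config.switch_time_h:
            for sp, y in config.acid_yields.items():
                prods[sp] += y * draw_total
        else:
            for sp, y in config.solvent_yields.items():
                prods[sp] += y * draw_total
            for sp in ("acetic_acid", "butyric_acid"):
                d_acid = min(prods[sp],
                             config.acid_reassimilation_rate * prods[sp] * config.dt)
                prods[sp] -= d_acid
                prods["butanol"] += config.reassimilation_yield * d_acid
            d_act = min(prods["acetone"],
                        config.acetone_conversion_rate * prods["acetone"] * config.dt)
            prods["acetone"] -= d_act
            prods["isopropanol"] += _ACT_TO_IPA * d_act

        X = X + config.dt * config.mu_max * X * (1.0 - X / config.biomass_capacity)
        record(i + 1)

    repeated = [sp for sp, k in floor_events.items() if k > 1]
    if repeated:
        logger.warning(
            "dt=%g h may be too large: substrate floored in multiple steps for %s",
            config.dt, ", ".join(repeated),
        )

    acids = traj["acetic_acid"] + traj["butyric_acid"]
    ph = np.clip(6.2 - 0.45 * acids, 4.5, 6.2)

    if latent or config.noise_sd == 0:
        return TimeCourse(times=times, series=traj, biomass=biomass, ph=ph)

    rng = np.random.default_rng(config.seed)
    noisy = {
        sp: np.maximum(0.0, v + rng.normal(0.0, config.noise_sd, v.shape))
        for sp, v in traj.items()
    }
    return TimeCourse(
        times=times, series=noisy, biomass=biomass, ph=ph,
        noise_tolerance=8.0 * config.noise_sd,
    )


def _split_draw(
    demand: float,
    subs: dict[str, float],
    glycerol_preference: float,
    floor_events: dict[str, int],
) -> dict[str, float]:
    """Split one step's substrate demand across the available substrates.

    While glycerol remains it supplies ``glycerol_preference`` of the
    demand; the remainder is shared over the other substrates in proportion
    to availability, and any shortfall falls back to glycerol. Draws never
    exceed what is available (floor events are counted for the dt check).
    """
    draws = {sp: 0.0 for sp in subs}
    others = [sp for sp in subs if sp != "glycerol"]
    gly_avail = subs.get("glycerol", 0.0)
    want_gly = demand * glycerol_preference if (gly_avail > 0 and others) else (
        demand if not others else 0.0
    )
    if "glycerol" in subs:
        draws["glycerol"] = min(want_gly, gly_avail)
        if gly_avail > 0 and want_gly > gly_avail:
            floor_events["glycerol"] += 1
    rest = demand - draws.get("glycerol", 0.0)
    avail = {sp: subs[sp] for sp in others}
    total_avail = sum(avail.values())
    if total_avail > 0 and rest > 0:
        if rest >= total_avail:
            for sp in others:
                draws[sp] = avail[sp]
                floor_events[sp] += 1
            rest -= total_avail
        else:
            for sp in others:
                draws[sp] = rest * avail[sp] / total_avail
            rest = 0.0
    if rest > 0 and "glycerol" in subs:
        room = gly_avail - draws["glycerol"]
        if room > 0:
            extra = min(rest, room)
            draws["glycerol"] += extra
            if extra < rest:
                floor_events["glycerol"] += 1
    return draws


def endpoint_from_timecourse(
    tc: TimeCourse, label: str = "simulation"
) -> EndpointRecord:
    """Endpoint record of a time course: net consumption, final titers, duration."""
    if len(tc) < 2 or tc.times[-1] <= 0:
        raise ComputationError("zero-duration time course")
    reg = default_registry()
    consumed: dict[str, float] = {}
    products: dict[str, float] = {}
    for sp_id, values in tc.series.items():
        sp = reg.get(sp_id)
        if sp.is_substrate:
            consumed[sp.id] = max(0.0, float(values[0] - values[-1]))
        else:
            products[sp.id] = float(values[-1])
    return EndpointRecord(
        label=label,
        duration_h=float(tc.times[-1]),
        substrates_consumed=consumed,
        products=products,
    )


# Preset scenarios calibrated so that a noiseless run lands near the endpoint
# tables bundled in ibferm.data (within ±15%); parameter values are fits to
# those endpoints, not biological measurements.
_SCENARIOS: dict[str, dict] = {
    "glucose_20": dict(
        initial_substrates={"glucose": 21.85},
        acid_yields={"acetic_acid": 0.2358, "butyric_acid": 0.3190},
        solvent_yields={"butanol": 0.1974, "isopropanol": 0.1058, "acetone": 0.0408},
        acid_reassimilation_rate=0.0252,
        acetone_conversion_rate=0.1048,
        t_end=28.0,
    ),
    "glucose_40": dict(
        initial_substrates={"glucose": 41.02},
        biomass_capacity=3.6,
        substrate_uptake_rate=0.80,
        acid_yields={"acetic_acid": 0.2358, "butyric_acid": 0.3190},
        solvent_yields={"butanol": 0.2110, "isopropanol": 0.0786, "acetone": 0.0408},
        acid_reassimilation_rate=0.0252,
        acetone_conversion_rate=0.1048,
        t_end=28.0,
    ),
    "mix_14_8": dict(
        initial_substrates={"glucose": 13.35, "glycerol": 7.01},
        glycerol_preference=0.34,
        acid_yields={"acetic_acid": 0.1007, "butyric_acid": 0.4111},
        solvent_yields={"butanol": 0.2865, "isopropanol": 0.0875, "acetone": 0.005},
        acid_reassimilation_rate=0.0198,
        acetone_conversion_rate=0.60,
        t_end=28.0,
    ),
    "glycerol_only": dict(
        initial_substrates={"glycerol": 18.13},
        acid_yields={"acetic_acid": 0.0794, "butyric_acid": 0.60},
        solvent_yields={"butanol": 0.2655, "pdo_13": 0.2309},
        acid_reassimilation_rate=0.0,
        t_end=28.0,
    ),
}


def scenario_names() -> tuple[str, ...]:
    return tuple(_SCENARIOS)


def scenario(name: str) -> SimConfig:
    """A documented preset :class:`SimConfig` by name.

    Presets: ``glucose_20`` (21.85 g/L glucose serum bottle),
    ``glucose_40`` (41 g/L glucose), ``mix_14_8`` (glucose:glycerol 14:8,
    acetone-free endpoint), ``glycerol_only`` (butanol + 1,3-propanediol
    route).
    """
    try:
        params = _SCENARIOS[name]
    except KeyError:
        raise ValidationError(
            f"unknown scenario {name!r}; available: {', '.join(_SCENARIOS)}"
        ) from None
    return SimConfig(**json.loads(json.dumps(params)))


def save_simulation(
    tc: TimeCourse, config: SimConfig, path: str | Path
) -> Path:
    """Write the time course as CSV plus an adjacent ``.meta.json``.

    The metadata always records the seed and dt along with the full config.
    """
    path = Path(path)
    write_timecourse(tc, path)
    meta = path.with_suffix(path.suffix + ".meta.json")
    meta.write_text(json.dumps(
        {"seed": config.seed, "dt": config.dt, "config": config.to_dict()},
        indent=2, sort_keys=True,
    ) + "\n")
    return meta
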
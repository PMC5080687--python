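"""Carbon- and NAD(P)H-balance metrics for IB fermentation endpoints.

Given one condition's net substrate consumption and final product titers,
this module computes the full set of derived metrics used to compare
isopropanol–butanol fermentations:

* mass yields Y_B and Y_IB (g product per g total consumed substrate) and
  overall volumetric productivities P_B, P_IB (final titer / duration);
* the butanol-to-isopropanol titer ratio B/I;
* total consumed carbon (mM C);
* NAD(P)H generated by glycolysis, 2 mol per mol of consumed glucose or
  glycerol — i.e. 1/3 per carbon of glucose and 2/3 per carbon of glycerol;
* NAD(P)H required by products: 4, 2, 1, 0, 0 mol per mol of butanol,
  butyric acid, isopropanol, acetone and acetic acid;
* NAD(P)H_C, generation per carbon-mole of consumed substrate;
* the ferredoxin fraction: the share of the NAD(P)H requirement not covered
  by glycolysis, attributed to re-oxidation of PFOR-reduced ferredoxin and
  clipped at zero when glycolytic generation already exceeds the demand;
* per-carbon-mole product formation (BuOH_C, IPA_C, IB_C, ACT_C, AA_C,
  BA_C) and percent carbon recovery into chosen product sets.

All metrics are returned at full precision; rounding is a display concern
(see :mod:`ibferm.report`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import CoefficientError, ComputationError, ValidationError
from .io import EndpointRecord, TimeCourse
from .registry import SpeciesRegistry, default_registry

__all__ = [
    "BalanceResult",
    "SOLVENTS",
    "ACIDS",
    "mass_yield",
    "productivity",
    "bi_ratio",
    "nadph_generated",
    "nadph_required",
    "nadph_per_cmol",
    "fd_fraction",
    "per_cmol_production",
    "carbon_recovery",
    "analyze_endpoint",
    "analyze_timecourse",
    "classify_mode",
]

#: Product sets used for phase classification and the standard summaries.
SOLVENTS = ("butanol", "isopropanol", "acetone")
ACIDS = ("acetic_acid", "butyric_acid")
IB = ("butanol", "isopropanol")

_PER_CMOL_NAMES = {
    "butanol": "buoh_c",
    "isopropanol": "ipa_c",
    "acetone": "act_c",
    "acetic_acid": "aa_c",
    "butyric_acid": "ba_c",
}


@dataclass
class BalanceResult:
    """All derived metrics for one fermentation condition.

    ``bi_ratio`` is None when the isopropanol titer is zero (undefined, not
    infinite); ``fd_fraction`` is None when the NAD(P)H requirement is zero.
    Any field set to None carries an explanatory entry in ``flags``.
    ``per_cmol`` maps ``buoh_c``/``ipa_c``/``ib_c``/``act_c``/``aa_c``/
    ``ba_c`` to mol product per C-mol consumed substrate (or C-mol per C-mol
    when computed with ``per_carbon=True``); ``carbon_recovery`` maps
    ``butanol``/``ib`` to percent of consumed carbon.
    """

    label: str
    y_b: float
    y_ib: float
    p_b: float
    p_ib: float
    bi_ratio: float | None
    total_carbon_mM: float
    nadph_gen_mM: float | None
    nadph_req_mM: float | None
    nadph_c: float | None
    fd_fraction: float | None
    per_cmol: dict[str, float]
    carbon_recovery: dict[str, float]
    mode: str
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, object]:
        """Flat mapping with the stable column names of the report layer."""
        out: dict[str, object] = {
            "label": self.label,
            "y_b": self.y_b,
            "y_ib": self.y_ib,
            "p_b": self.p_b,
            "p_ib": self.p_ib,
            "bi_ratio": self.bi_ratio,
            "total_carbon_mM": self.total_carbon_mM,
            "nadph_gen_mM": self.nadph_gen_mM,
            "nadph_req_mM": self.nadph_req_mM,
            "nadph_c": self.nadph_c,
            "fd_fraction": self.fd_fraction,
            "cr_butanol_pct": self.carbon_recovery["butanol"],
            "cr_ib_pct": self.carbon_recovery["ib"],
            "mode": self.mode,
        }
        out.update(self.per_cmol)
        return out


def _registry(registry: SpeciesRegistry | None) -> SpeciesRegistry:
    return registry if registry is not None else default_registry()


def mass_yield(
    record: EndpointRecord,
    product_set: Iterable[str] = ("butanol",),
    registry: SpeciesRegistry | None = None,
) -> float:
    """g of the product set per g of total consumed substrate (mixed feeds included)."""
    consumed = record.total_substrate_g
    if consumed <= 0:
        raise ComputationError(f"{record.label!r}: zero substrate consumption")
    return sum(record.product_titer(sp) for sp in product_set) / consumed


def productivity(
    record: EndpointRecord,
    product_set: Iterable[str] = ("butanol",),
) -> float:
    """Overall volumetric productivity: summed final titer / duration (g/L/h)."""
    if not (record.duration_h > 0):
        raise ComputationError(f"{record.label!r}: missing or zero duration")
    return sum(record.product_titer(sp) for sp in product_set) / record.duration_h


def bi_ratio(record: EndpointRecord) -> float | None:
    """Butanol titer / isopropanol titer (g/g); None when isopropanol is zero."""
    ipa = record.product_titer("isopropanol")
    if ipa <= 0:
        return None
    return record.product_titer("butanol") / ipa


def nadph_generated(
    record: EndpointRecord, registry: SpeciesRegistry | None = None
) -> float:
    """NAD(P)H generated by glycolysis from the consumed substrates, mM.

    Each consumed substrate contributes coefficient × mM consumed. Every
    substrate with non-zero consumption must carry a core generation
    coefficient (glucose and glycerol do; sugars outside the glucose/
    glycerol balance do not and raise :class:`CoefficientError`).
    """
    reg = _registry(registry)
    total = 0.0
    for sp_id, conc in record.substrates_consumed.items():
        if conc == 0:
            continue
        sp = reg.get(sp_id)
        if sp.nadph_gen_per_mol is None or sp.redox_status != "core":
            raise CoefficientError(
                f"{record.label!r}: no core NAD(P)H generation coefficient for "
                f"substrate {sp.id!r}"
            )
        total += sp.nadph_gen_per_mol * reg.to_millimolar(conc, sp_id)
    return total


def nadph_required(
    record: EndpointRecord,
    registry: SpeciesRegistry | None = None,
    allow_extrapolated: bool = False,
) -> float:
    """NAD(P)H required to form the products, mM.

    Σ coefficient × mM produced, with the core coefficients 4 (butanol),
    2 (butyric acid), 1 (isopropanol), 0 (acetone), 0 (acetic acid).
    Ethanol is excluded from the balance (titers in the emulated study were
    below the 0.1 g/L detection threshold). Products whose coefficient is
    package-extrapolated (1,3-propanediol) raise :class:`CoefficientError`
    unless ``allow_extrapolated`` is set.
    """
    reg = _registry(registry)
    total = 0.0
    for sp_id, conc in record.products.items():
        if conc == 0:
            continue
        sp = reg.get(sp_id)
        if sp.id == "ethanol":
            continue
        if sp.nadph_req_per_mol is None:
            raise CoefficientError(
                f"{record.label!r}: no NAD(P)H requirement coefficient for "
                f"product {sp.id!r}"
            )
        if sp.redox_status != "core" and not allow_extrapolated:
            raise CoefficientError(
                f"{record.label!r}: coefficient for {sp.id!r} is extrapolated; "
                f"pass allow_extrapolated=True to use it"
            )
        total += sp.nadph_req_per_mol * reg.to_millimolar(conc, sp_id)
    return total


def _total_carbon(record: EndpointRecord, reg: SpeciesRegistry) -> float:
    return reg.total_carbon_millimolar(record.substrates_consumed)


def nadph_per_cmol(
    record: EndpointRecord, registry: SpeciesRegistry | None = None
) -> float:
    """NAD(P)H_C: mol NAD(P)H generated per carbon-mole of consumed substrate.

    1/3 exactly for a pure-glucose feed, 2/3 for pure glycerol.
    """
    reg = _registry(registry)
    carbon = _total_carbon(record, reg)
    if carbon <= 0:
        raise ComputationError(f"{record.label!r}: zero consumed carbon")
    return nadph_generated(record, reg) / carbon


def fd_fraction(
    record: EndpointRecord, registry: SpeciesRegistry | None = None
) -> float:
    """Fraction of the NAD(P)H requirement attributed to reduced ferredoxin.

    ``max(0, required − generated) / required``: the glycolytic supply is
    subtracted from the product demand and any shortfall is assigned to
    NAD(P)H regenerated from Fd_red via PFOR. A surplus clips to 0 rather
    than reporting a negative fraction.
    """
    reg = _registry(registry)
    req = nadph_required(record, reg)
    if req <= 0:
        raise ComputationError(f"{record.label!r}: zero NAD(P)H requirement")
    return max(0.0, req - nadph_generated(record, reg)) / req


def per_cmol_production(
    record: EndpointRecord,
    registry: SpeciesRegistry | None = None,
    per_carbon: bool = False,
) -> dict[str, float]:
    """Product formation per carbon-mole of consumed substrate.

    Default units are mol product per C-mol substrate; with
    ``per_carbon=True`` each entry is multiplied by the product's carbon
    count, giving C-mol per C-mol. ``ib_c`` is ``buoh_c + ipa_c``.
    """
    reg = _registry(registry)
    carbon = _total_carbon(record, reg)
    if carbon <= 0:
        raise ComputationError(f"{record.label!r}: zero consumed carbon")
    out: dict[str, float] = {}
    for sp_id, key in _PER_CMOL_NAMES.items():
        mm = reg.to_millimolar(record.product_titer(sp_id), sp_id)
        if per_carbon:
            mm *= reg.get(sp_id).carbon_atoms
        out[key] = mm / carbon
    out["ib_c"] = out["buoh_c"] + out["ipa_c"]
    return out


def carbon_recovery(
    record: EndpointRecord,
    product_set: Iterable[str] = IB,
    registry: SpeciesRegistry | None = None,
) -> float:
    """Percent of consumed substrate carbon recovered in the product set."""
    reg = _registry(registry)
    carbon = _total_carbon(record, reg)
    if carbon <= 0:
        raise ComputationError(f"{record.label!r}: zero consumed carbon")
    recovered = sum(
        reg.carbon_millimolar(record.product_titer(sp), sp) for sp in product_set
    )
    return 100.0 * recovered / carbon


def classify_mode(record: EndpointRecord) -> str:
    """``"acidogenic"`` when total acids (g/L) exceed total solvents, else
    ``"solventogenic"`` (a tie counts as solventogenic, with a warning)."""
    acids = sum(record.product_titer(sp) for sp in ACIDS)
    solvents = sum(record.product_titer(sp) for sp in SOLVENTS)
    if acids > solvents:
        return "acidogenic"
    if acids == solvents:
        warnings.warn(
            f"{record.label!r}: acids equal solvents ({acids} g/L); "
            "classified solventogenic by the tie rule",
            stacklevel=2,
        )
    return "solventogenic"


def analyze_endpoint(
    record: EndpointRecord,
    registry: SpeciesRegistry | None = None,
    allow_extrapolated: bool = False,
    per_carbon: bool = False,
) -> BalanceResult:
    """Compute every balance metric for one endpoint.

    Every field equals the output of its dedicated operation. Metrics whose
    precondition fails on this record (zero NAD(P)H requirement, undefined
    B/I, missing coefficients) are set to None with a message in ``flags``
    naming the field; hard input errors still raise.
    """
    reg = _registry(registry)
    flags: list[str] = []

    def _try(fieldname, fn):
        try:
            return fn()
        except (ComputationError, CoefficientError) as exc:
            flags.append(f"{fieldname}: {exc}")
            return None

    ratio = bi_ratio(record)
    if ratio is None:
        flags.append("bi_ratio: undefined (zero isopropanol titer)")
    gen = _try("nadph_gen_mM", lambda: nadph_generated(record, reg))
    req = _try(
        "nadph_req_mM", lambda: nadph_required(record, reg, allow_extrapolated)
    )
    return BalanceResult(
        label=record.label,
        y_b=mass_yield(record, ("butanol",), reg),
        y_ib=mass_yield(record, IB, reg),
        p_b=productivity(record, ("butanol",)),
        p_ib=productivity(record, IB),
        bi_ratio=ratio,
        total_carbon_mM=_total_carbon(record, reg),
        nadph_gen_mM=gen,
        nadph_req_mM=req,
        nadph_c=_try("nadph_c", lambda: nadph_per_cmol(record, reg)),
        fd_fraction=_try("fd_fraction", lambda: fd_fraction(record, reg)),
        per_cmol=per_cmol_production(record, reg, per_carbon=per_carbon),
        carbon_recovery={
            "butanol": carbon_recovery(record, ("butanol",), reg),
            "ib": carbon_recovery(record, IB, reg),
        },
        mode=classify_mode(record),
        flags=flags,
    )


def endpoint_at_time(
    tc: TimeCourse,
    at_time: float,
    label: str | None = None,
    registry: SpeciesRegistry | None = None,
) -> EndpointRecord:
    """Extract an :class:`EndpointRecord` from a time course at ``at_time``.

    Consumption is ``series[0] − series(at_time)`` for substrate-role
    species (linear interpolation between samples, small noise-induced
    negatives clipped to 0); products are titers at ``at_time``.
    """
    reg = _registry(registry)
    if at_time <= 0:
        raise ComputationError("at_time must be > 0 (zero consumption at t=0)")
    values = tc.at(at_time)
    consumed: dict[str, float] = {}
    products: dict[str, float] = {}
    for sp_id, now in values.items():
        sp = reg.get(sp_id)
        if sp.is_substrate:
            consumed[sp.id] = max(0.0, float(tc.series[sp_id][0]) - now)
        else:
            products[sp.id] = max(0.0, now)
    return EndpointRecord(
        label=label or f"t={at_time:g}h",
        duration_h=float(at_time),
        substrates_consumed=consumed,
        products=products,
    )


def analyze_timecourse(
    tc: TimeCourse,
    at_time: float,
    registry: SpeciesRegistry | None = None,
    **kwargs,
) -> BalanceResult:
    """:func:`analyze_endpoint` of the record extracted at ``at_time``."""
    record = endpoint_at_time(tc, at_time, registry=registry)
    if record.total_substrate_g <= 0:
        raise ComputationError(f"no substrate consumed by t={at_time:g} h")
    return analyze_endpoint(record, registry=registry, **kwargs)
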
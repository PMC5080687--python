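"""Chemical species registry and unit conversions.

The registry is the single authority for molar masses, carbon counts and the
NAD(P)H stoichiometric coefficients used throughout the balance engine:

* substrates entering glycolysis generate 2 mol NAD(P)H per mol consumed
  (glucose via the EMP pathway, glycerol via glycerol dehydrogenase + lower
  glycolysis), i.e. 1/3 NAD(P)H per carbon for glucose and 2/3 for glycerol;
* products consume 4, 2, 1, 0 and 0 mol NAD(P)H per mol of butanol,
  butyric acid, isopropanol, acetone and acetic acid formed from acetyl-CoA.

Coefficients carry a ``redox_status``: ``core`` values are part of the
canonical clostridial bookkeeping above; ``extrapolated`` values (e.g. 1 mol
per mol of 1,3-propanediol from glycerol) are package-supplied defaults that
balance computations refuse to use unless explicitly enabled.

Molar masses are registry constants chosen to match the conversion factors
conventionally used in fermentation balance tables (glucose 180.2 g/mol).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

from .errors import UnknownSpeciesError, ValidationError

__all__ = [
    "Species",
    "SpeciesRegistry",
    "default_registry",
    "get_species",
    "to_millimolar",
    "carbon_millimolar",
]


@dataclass(frozen=True)
class Species:
    """Immutable chemical descriptor of one substrate or product.

    Parameters
    ----------
    id : str
        Canonical lower-case name, e.g. ``"glucose"``, ``"butyric_acid"``.
    molar_mass : float
        g/mol, > 0.
    carbon_atoms : int
        Carbon atoms per molecule, >= 1.
    role : str
        ``"substrate"``, ``"product"`` or ``"both"``.
    nadph_gen_per_mol : float or None
        mol NAD(P)H generated per mol consumed (substrates; None if unknown).
    nadph_req_per_mol : float or None
        mol NAD(P)H required per mol produced (products; None if unknown).
    redox_status : str
        ``"core"`` if the coefficient belongs to the canonical bookkeeping,
        ``"extrapolated"`` for package-supplied defaults.
    aliases : tuple of str
        Alternative names accepted by lookups (case-insensitive).
    """

    id: str
    molar_mass: float
    carbon_atoms: int
    role: str
    nadph_gen_per_mol: float | None = None
    nadph_req_per_mol: float | None = None
    redox_status: str = "core"
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValidationError(f"{self.id}: molar_mass must be > 0")
        if self.carbon_atoms < 1:
            raise ValidationError(f"{self.id}: carbon_atoms must be >= 1")
        if self.role not in ("substrate", "product", "both"):
            raise ValidationError(f"{self.id}: invalid role {self.role!r}")

    @property
    def is_substrate(self) -> bool:
        return self.role in ("substrate", "both")

    @property
    def is_product(self) -> bool:
        return self.role in ("product", "both")


class SpeciesRegistry:
    """Lookup table of :class:`Species`, keyed by id or alias (case-insensitive)."""

    def __init__(self, species: list[Species]):
        self._species: dict[str, Species] = {}
        self._index: dict[str, str] = {}
        for sp in species:
            if sp.id in self._species:
                raise ValidationError(f"duplicate species id {sp.id!r}")
            self._species[sp.id] = sp
            for key in (sp.id, *sp.aliases):
                self._index[key.lower()] = sp.id

    def get(self, species_id: str) -> Species:
        """Return the descriptor for ``species_id`` (id or alias).

        Raises
        ------
        UnknownSpeciesError
            If the id is not registered.
        """
        canonical = self._index.get(str(species_id).lower())
        if canonical is None:
            raise UnknownSpeciesError(species_id, tuple(self._species))
        return self._species[canonical]

    def __contains__(self, species_id: str) -> bool:
        return str(species_id).lower() in self._index

    def __iter__(self) -> Iterator[Species]:
        return iter(self._species.values())

    def ids(self) -> tuple[str, ...]:
        return tuple(self._species)

    def resolve(self, species_id: str) -> str:
        """Canonical id for an id or alias."""
        return self.get(species_id).id

    def to_millimolar(self, conc_g_per_l: float, species_id: str) -> float:
        """Convert a mass concentration (g/L) to millimolar.

        Exact arithmetic ``conc * 1000 / molar_mass``; no rounding.
        """
        if conc_g_per_l < 0:
            raise ValidationError(
                f"negative concentration {conc_g_per_l} g/L for {species_id!r}"
            )
        sp = self.get(species_id)
        return conc_g_per_l * 1000.0 / sp.molar_mass

    def carbon_millimolar(self, conc_g_per_l: float, species_id: str) -> float:
        """Convert a mass concentration (g/L) to millimolar of carbon."""
        sp = self.get(species_id)
        return self.to_millimolar(conc_g_per_l, species_id) * sp.carbon_atoms

    def total_carbon_millimolar(self, concs: Mapping[str, float]) -> float:
        """Summed carbon-mM over a ``{species: g/L}`` map."""
        return sum(self.carbon_millimolar(c, sp) for sp, c in concs.items())

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpeciesRegistry":
        """Load a registry from a delimited text table.

        Columns: id, aliases (``;``-separated), molar_mass, carbon_atoms,
        role, nadph_gen_per_mol, nadph_req_per_mol, redox_status.
        """
        species = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                species.append(
                    Species(
                        id=row["id"].strip(),
                        molar_mass=float(row["molar_mass"]),
                        carbon_atoms=int(row["carbon_atoms"]),
                        role=row["role"].strip(),
                        nadph_gen_per_mol=_opt_float(row.get("nadph_gen_per_mol")),
                        nadph_req_per_mol=_opt_float(row.get("nadph_req_per_mol")),
                        redox_status=row.get("redox_status", "core").strip(),
                        aliases=tuple(
                            a.strip() for a in (row.get("aliases") or "").split(";") if a.strip()
                        ),
                    )
                )
        return cls(species)


def _opt_float(value: str | None) -> float | None:
    if value is None or value.strip() == "":
        return None
    return float(value)


_DEFAULT: SpeciesRegistry | None = None


def default_registry() -> SpeciesRegistry:
    """The bundled registry (loaded once per process)."""
    global _DEFAULT
    if _DEFAULT is None:
        with resources.as_file(
            resources.files("ibferm.data").joinpath("species.csv")
        ) as path:
            _DEFAULT = SpeciesRegistry.from_csv(path)
    return _DEFAULT


def get_species(species_id: str) -> Species:
    """Descriptor lookup in the bundled registry (id or alias, any case)."""
    return default_registry().get(species_id)


def to_millimolar(conc_g_per_l: float, species_id: str) -> float:
    """g/L → mM in the bundled registry."""
    return default_registry().to_millimolar(conc_g_per_l, species_id)


def carbon_millimolar(conc_g_per_l: float, species_id: str) -> float:
    """g/L → mM carbon in the bundled registry."""
    return default_registry().carbon_millimolar(conc_g_per_l, species_id)
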
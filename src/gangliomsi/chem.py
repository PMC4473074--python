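"""Theoretical monoisotopic masses and negative-mode adduct m/z for A-series gangliosides.

A-series gangliosides are built by stepwise glycosylation of a ceramide
anchor: GM3 (Hex-Hex-NeuAc) -> GM2 (+HexNAc) -> GM1 (+Hex) -> GD1a (+NeuAc).
Brain gangliosides occur with two dominant sphingoid backbones, d18:1 and
d20:1, which differ by one C2H4 unit.  In negative-mode MALDI the
mono-sialylated species ionize as [M-H]-, while the di-sialylated GD1a is
observed as the singly charged sodium and potassium salt adducts
[M-2H+Na]- and [M-2H+K]-.

Masses are computed by summing dehydrated glycosyl residue masses onto the
ceramide mass; all values derive from the embedded IUPAC/CODATA monoisotopic
atomic mass table below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Adduct",
    "Ceramide",
    "GangliosideSpecies",
    "IonSpecies",
    "PanelConfigError",
    "ResidueComposition",
    "adduct_mz",
    "build_panel",
    "default_panel_config",
    "load_panel_config",
    "neutral_mass",
    "species_from_name",
]

# Monoisotopic atomic masses, Da (IUPAC 2021 atomic mass evaluation; electron
# mass from CODATA).  Embedded as constants: no network lookup.
ATOMIC_MASS: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
    "K": 38.96370668,
}
ELECTRON_MASS = 0.00054857990946

_H = ATOMIC_MASS["H"]

# Dehydrated glycosyl residue masses (the mass each residue adds when joined
# by a glycosidic bond, i.e. the free monosaccharide minus one water).
HEX_RESIDUE = 6 * ATOMIC_MASS["C"] + 10 * _H + 5 * ATOMIC_MASS["O"]          # C6H10O5
HEXNAC_RESIDUE = 8 * ATOMIC_MASS["C"] + 13 * _H + ATOMIC_MASS["N"] + 5 * ATOMIC_MASS["O"]   # C8H13NO5
NEUAC_RESIDUE = 11 * ATOMIC_MASS["C"] + 17 * _H + ATOMIC_MASS["N"] + 8 * ATOMIC_MASS["O"]   # C11H17NO8

# Ceramide (sphingoid base amide-linked to the N-acyl chain, one water lost).
# d18:1/18:0 = C36H71NO3; each backbone carbon pair adds C2H4.
_CERAMIDE_D18_18_0 = 36 * ATOMIC_MASS["C"] + 71 * _H + ATOMIC_MASS["N"] + 3 * ATOMIC_MASS["O"]
C2H4 = 2 * ATOMIC_MASS["C"] + 4 * _H


class ConfigurationError(ValueError):
    """A species, ceramide or adduct request outside the supported panel chemistry."""


class PanelConfigError(ConfigurationError):
    """Invalid panel configuration (unknown names or colliding integration windows)."""


class Adduct(str, Enum):
    """Singly charged negative-mode adducts observed for the panel."""

    DEPROTONATED = "[M-H]-"
    SODIATED = "[M-2H+Na]-"
    POTASSIATED = "[M-2H+K]-"

    @property
    def mass_delta(self) -> float:
        """Mass added to the neutral molecule to form the (charge -1) anion."""
        if self is Adduct.DEPROTONATED:
            return -_H + ELECTRON_MASS
        if self is Adduct.SODIATED:
            return -2 * _H + ATOMIC_MASS["Na"] + ELECTRON_MASS
        return -2 * _H + ATOMIC_MASS["K"] + ELECTRON_MASS


@dataclass(frozen=True)
class ResidueComposition:
    """Counts of glycosyl building blocks attached to the ceramide."""

    hex_count: int
    hexnac_count: int
    neuac_count: int

    def __post_init__(self) -> None:
        if min(self.hex_count, self.hexnac_count, self.neuac_count) < 0:
            raise ConfigurationError("residue counts must be non-negative")
        if self.hexnac_count >= 1 and self.hex_count < 2:
            raise ConfigurationError(
                "A-series composition requires the lactosylceramide core "
                "(hex_count >= 2) before HexNAc can be attached"
            )

    @property
    def mass(self) -> float:
        return (
            self.hex_count * HEX_RESIDUE
            + self.hexnac_count * HEXNAC_RESIDUE
            + self.neuac_count * NEUAC_RESIDUE
        )


#: glycan composition of each A-series species
_SPECIES_RESIDUES: Mapping[str, ResidueComposition] = {
    "GM3": ResidueComposition(hex_count=2, hexnac_count=0, neuac_count=1),
    "GM2": ResidueComposition(hex_count=2, hexnac_count=1, neuac_count=1),
    "GM1": ResidueComposition(hex_count=3, hexnac_count=1, neuac_count=1),
    "GD1a": ResidueComposition(hex_count=3, hexnac_count=1, neuac_count=2),
}

#: sphingoid backbone carbon count for each supported base label
_BASE_CARBONS: Mapping[str, int] = {"d18:1": 18, "d20:1": 20}


@dataclass(frozen=True)
class Ceramide:
    """Ceramide anchor: sphingoid base (d18:1 or d20:1) plus a fixed N-acyl chain.

    The N-acyl chain defaults to stearoyl (18:0), the dominant acyl of adult
    brain gangliosides; other saturated chains may be configured via
    ``acyl_label`` ("16:0" ... "24:0").
    """

    base_label: str = "d18:1"
    acyl_label: str = "18:0"

    def __post_init__(self) -> None:
        if self.base_label not in _BASE_CARBONS:
            raise ConfigurationError(
                f"unknown sphingoid base {self.base_label!r}; supported: "
                f"{sorted(_BASE_CARBONS)}"
            )
        carbons, _, unsat = self.acyl_label.partition(":")
        try:
            if int(unsat) != 0 or not 2 <= int(carbons) <= 30:
                raise ValueError
        except ValueError:
            raise ConfigurationError(
                f"unsupported N-acyl chain {self.acyl_label!r}; expected a "
                "saturated chain label like '18:0'"
            ) from None

    @property
    def mass(self) -> float:
        """Monoisotopic mass of the ceramide (Da)."""
        base_extra = _BASE_CARBONS[self.base_label] - 18
        acyl_extra = int(self.acyl_label.partition(":")[0]) - 18
        return _CERAMIDE_D18_18_0 + (base_extra + acyl_extra) // 2 * C2H4


@dataclass(frozen=True)
class GangliosideSpecies:
    """One neutral ganglioside molecule: glycan class plus ceramide variant."""

    name: str
    ceramide: Ceramide = field(default_factory=Ceramide)

    def __post_init__(self) -> None:
        if self.name not in _SPECIES_RESIDUES:
            raise ConfigurationError(
                f"unknown ganglioside {self.name!r}; supported: "
                f"{sorted(_SPECIES_RESIDUES)}"
            )

    @property
    def residues(self) -> ResidueComposition:
        return _SPECIES_RESIDUES[self.name]

    @property
    def label(self) -> str:
        return f"{self.name} {self.ceramide.base_label}"


def species_from_name(name: str, base_label: str = "d18:1", acyl_label: str = "18:0") -> GangliosideSpecies:
    return GangliosideSpecies(name=name, ceramide=Ceramide(base_label, acyl_label))


def neutral_mass(species: GangliosideSpecies) -> float:
    """Monoisotopic mass (Da) of the neutral ganglioside.

    Sum of the ceramide mass and the dehydrated residue masses of the glycan.
    """
    return species.ceramide.mass + species.residues.mass


@dataclass(frozen=True)
class IonSpecies:
    """A panel ion channel: ganglioside + adduct, with theoretical m/z and window."""

    species: GangliosideSpecies
    adduct: Adduct
    mz: float
    window: float = 0.5
    charge: int = -1

    @property
    def label(self) -> str:
        return f"{self.species.label} {self.adduct.value}"

    @property
    def window_bounds(self) -> tuple[float, float]:
        return (self.mz - self.window, self.mz + self.window)


def adduct_mz(species: GangliosideSpecies, adduct: Adduct, window: float = 0.5) -> IonSpecies:
    """Theoretical m/z of a singly charged negative-mode adduct ion.

    Doubly charged ions ([M-2H]2-) are not supported: in tissue, the
    di-sialylated GD1a is observed as singly charged Na+/K+ salt adducts
    rather than as the doubly deprotonated anion.
    """
    if not isinstance(adduct, Adduct):
        raise ConfigurationError(f"unsupported adduct {adduct!r}")
    mz = (neutral_mass(species) + adduct.mass_delta) / 1.0
    return IonSpecies(species=species, adduct=adduct, mz=mz, window=window)


#: The default quantification panel: the mono-sialo species as [M-H]- for both
#: ceramides, and GD1a as its Na+ and K+ adducts for both ceramides (10 ions).
DEFAULT_PANEL_CONFIG: Mapping[str, object] = {
    "window": 0.5,
    "acyl": "18:0",
    "ceramides": ["d18:1", "d20:1"],
    "ions": [
        {"species": "GM3", "adducts": ["[M-H]-"]},
        {"species": "GM2", "adducts": ["[M-H]-"]},
        {"species": "GM1", "adducts": ["[M-H]-"]},
        {"species": "GD1a", "adducts": ["[M-2H+Na]-", "[M-2H+K]-"]},
    ],
}


def default_panel_config() -> dict:
    return yaml.safe_load(yaml.safe_dump(dict(DEFAULT_PANEL_CONFIG)))


def load_panel_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "ions" not in config:
        raise PanelConfigError(f"panel config {path} must define an 'ions' list")
    return config


def build_panel(config: Mapping[str, object] | None = None) -> list[IonSpecies]:
    """Build the sorted ion panel from a configuration mapping.

    Returns ions sorted by m/z.  Raises :class:`PanelConfigError` when two
    integration windows overlap (the half-width must be small enough that
    adjacent channels stay disjoint).
    """
    if config is None:
        config = default_panel_config()
    window = float(config.get("window", 0.5))
    if window <= 0:
        raise PanelConfigError("window half-width must be positive")
    acyl = str(config.get("acyl", "18:0"))
    ceramides = list(config.get("ceramides", ["d18:1", "d20:1"]))

    ions: list[IonSpecies] = []
    for entry in config["ions"]:
        name = entry["species"]
        adducts = [Adduct(a) for a in entry.get("adducts", ["[M-H]-"])]
        entry_ceramides = list(entry.get("ceramides", ceramides))
        for base in entry_ceramides:
            species = species_from_name(name, base, acyl)
            for adduct in adducts:
                ions.append(adduct_mz(species, adduct, window=window))

    ions.sort(key=lambda ion: ion.mz)
    for a, b in zip(ions, ions[1:]):
        if a.mz + a.window > b.mz - b.window:
            raise PanelConfigError(
                f"integration windows overlap between {a.label} (m/z {a.mz:.4f}) "
                f"and {b.label} (m/z {b.mz:.4f}) at half-width {window} Da"
            )
    return ions


def panel_table(ions: Iterable[IonSpecies]) -> str:
    """Delimited table of the panel: name, adduct, theoretical m/z, window."""
    lines = ["species\tceramide\tadduct\tmz\twindow"]
    for ion in ions:
        lines.append(
            f"{ion.species.name}\t{ion.species.ceramide.base_label}\t"
            f"{ion.adduct.value}\t{ion.mz:.4f}\t{ion.window:.3f}"
        )
    return "\n".join(lines)
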
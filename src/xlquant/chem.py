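"""Mass arithmetic for cross-linked peptide species.

Implements the neutral-mass bookkeeping for peptides joined by a cleavable,
amine-reactive cross-linker.  After enrichment and chemical cleavage the
linker leaves a constant residual mass on the linked peptides; the
deuterium-coded form of the linker adds a fixed label delta (six 2H-for-1H
substitutions in the spacer arm).  Three species types are handled:

* ``inter``  — two peptides joined by one linker,
* ``loop``   — both linker ends on the same peptide,
* ``mono``   — one end reacted, the other quenched/hydrolyzed.

All masses are monoisotopic and in daltons.  Charge arithmetic uses the
proton mass without electron correction, which reproduces the published
worked example for the bAL2 linker (MH+ 4433.0553 for the
NYQEAKDAFLGSFLYEYSR x LAKEYEATLEECCAK pair with carbamidomethylated
cysteines).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "MassTable",
    "LinkerSpec",
    "LinkType",
    "Channel",
    "LinkedSpecies",
    "Ms2Spectrum",
    "ReporterCheck",
    "peptide_mass",
    "species_mass",
    "mz_from_mass",
    "composition_mass",
    "protonated_mz",
    "verify_reporter",
    "builtin_linker",
    "BUILTIN_LINKERS",
    "CARBAMIDOMETHYL",
    "OXIDATION",
]

# Fixed/variable modification deltas mirroring common search settings (Da).
CARBAMIDOMETHYL = 57.02146   # iodoacetamide-alkylated Cys
OXIDATION = 15.99491         # oxidized Met

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def _nist(element: str, isotope: int = 0) -> float:
    return _pmass.nist_mass[element][isotope][0]


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic residue and element masses.

    Defaults are taken from the NIST atomic mass tables shipped with
    pyteomics; the proton mass is the conventional 1.007276 Da used for all
    charge arithmetic (electron mass otherwise ignored).
    """

    residue_masses: dict[str, float] = field(
        default_factory=lambda: dict(_pmass.std_aa_mass)
    )
    element_masses: dict[str, float] = field(
        default_factory=lambda: {
            "H": _nist("H", 1),
            "D": _nist("H", 2),
            "2H": _nist("H", 2),
            "C": _nist("C", 12),
            "N": _nist("N", 14),
            "O": _nist("O", 16),
            "S": _nist("S", 32),
        }
    )
    water_mass: float = 2 * _nist("H", 1) + _nist("O", 16)
    proton_mass: float = 1.007276

    def __post_init__(self) -> None:
        missing = [r for r in _STANDARD_RESIDUES if r not in self.residue_masses]
        if missing:
            raise ValueError(f"mass table lacks standard residues: {missing}")
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("residue masses must be positive")
        expected_water = 2 * self.element_masses["H"] + self.element_masses["O"]
        if abs(self.water_mass - expected_water) > 1e-6:
            raise ValueError("water_mass inconsistent with element masses")

    @property
    def label_delta_d6(self) -> float:
        """Mass added by six 2H-for-1H substitutions in the spacer arm."""
        return 6.0 * (self.element_masses["D"] - self.element_masses["H"])


DEFAULT_MASS_TABLE = MassTable()


@dataclass(frozen=True)
class LinkerSpec:
    """A cross-linker definition.

    ``inter_residual_mass_d0`` is the mass added to the sum of the two
    peptide masses by one (cleaved, for cleavable linkers) cross-link in the
    light channel.  ``reporter_mz`` is the diagnostic HCD fragment, if the
    linker produces one.  The Calpha cutoffs encode the spacer-arm reach plus
    two lysine side chains (strict) and a conformational-flexibility
    allowance (relaxed).
    """

    name: str
    inter_residual_mass_d0: float
    monolink_residual_mass_d0: float
    label_delta: float = 0.0
    reporter_mz: Optional[float] = None
    spacer_length: float = 0.0
    calpha_cutoff_strict: float = 22.0
    calpha_cutoff_relaxed: float = 30.0

    def __post_init__(self) -> None:
        if self.calpha_cutoff_strict >= self.calpha_cutoff_relaxed:
            raise ValueError("strict cutoff must be below relaxed cutoff")
        if self.reporter_mz is not None and self.reporter_mz <= 0:
            raise ValueError("reporter_mz must be positive")


# bAL2 inter-link residual: back-computed from the published worked example
# (MH+ 4433.0553) by subtracting both peptide masses and one proton.
BAL2_INTER_RESIDUAL = 318.1505
_WATER = DEFAULT_MASS_TABLE.water_mass
_D6 = DEFAULT_MASS_TABLE.label_delta_d6
REPORTER_MZ = 122.0606  # protonated C7H7NO, no electron correction

_BAL2 = LinkerSpec(
    name="bAL2",
    inter_residual_mass_d0=BAL2_INTER_RESIDUAL,
    monolink_residual_mass_d0=BAL2_INTER_RESIDUAL + _WATER,
    label_delta=_D6,
    reporter_mz=REPORTER_MZ,
    spacer_length=9.3,
)

BUILTIN_LINKERS: dict[str, LinkerSpec] = {
    "bAL2": _BAL2,
    # bAL1 leaves the same cleaved residual; the two designs are
    # interchangeable in practice.
    "bAL1": replace(_BAL2, name="bAL1"),
    # Heavy-channel search variant: the d0 residual already carries the label.
    "d6-bAL2": replace(
        _BAL2,
        name="d6-bAL2",
        inter_residual_mass_d0=BAL2_INTER_RESIDUAL + _D6,
        monolink_residual_mass_d0=BAL2_INTER_RESIDUAL + _WATER + _D6,
    ),
    # Conventional non-enrichable control linker (suberate residual); no
    # reporter ion, longer spacer.
    "BS3": LinkerSpec(
        name="BS3",
        inter_residual_mass_d0=138.06808,
        monolink_residual_mass_d0=138.06808 + _WATER,
        label_delta=0.0,
        reporter_mz=None,
        spacer_length=11.4,
        calpha_cutoff_strict=24.0,
        calpha_cutoff_relaxed=30.0,
    ),
}


def builtin_linker(name: str) -> LinkerSpec:
    try:
        return BUILTIN_LINKERS[name]
    except KeyError:
        raise KeyError(
            f"unknown linker {name!r}; built-ins: {sorted(BUILTIN_LINKERS)}"
        ) from None


class LinkType(str, Enum):
    INTER = "inter"
    LOOP = "loop"
    MONO = "mono"


class Channel(str, Enum):
    D0 = "d0"
    D6 = "d6"


@dataclass(frozen=True)
class LinkedSpecies:
    """A peptide or peptide pair carrying one cross-link.

    ``modifications`` entries are ``(peptide_id, position, mass_delta)``
    with peptide_id 0 for peptide_a and 1 for peptide_b, positions 1-based.
    Link sites must point at a lysine or the peptide N-terminus (position 1).
    """

    link_type: LinkType
    peptide_a: str
    site_a: int
    peptide_b: str = ""
    site_b: Optional[int] = None
    modifications: tuple[tuple[int, int, float], ...] = ()
    charge: int = 1
    channel: Channel = Channel.D0

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.link_type is LinkType.INTER:
            if not self.peptide_b:
                raise ValueError("inter-linked species needs peptide_b")
            if self.site_b is None:
                raise ValueError("inter-linked species needs site_b")
        if self.link_type is LinkType.LOOP:
            if self.site_b is None or self.site_b == self.site_a:
                raise ValueError("loop link needs two distinct sites on peptide_a")
        self._check_site(self.peptide_a, self.site_a, "site_a")
        if self.link_type is LinkType.INTER:
            self._check_site(self.peptide_b, self.site_b, "site_b")
        elif self.link_type is LinkType.LOOP:
            self._check_site(self.peptide_a, self.site_b, "site_b")

    @staticmethod
    def _check_site(peptide: str, site: int, label: str) -> None:
        if not 1 <= site <= len(peptide):
            raise ValueError(f"{label}={site} outside peptide of length {len(peptide)}")
        if peptide[site - 1] != "K" and site != 1:
            raise ValueError(
                f"{label}={site} points at {peptide[site - 1]!r}; link sites must "
                "be lysine or the peptide N-terminus"
            )


def peptide_mass(
    sequence: str,
    mods: Sequence[tuple[int, float]] = (),
    table: MassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Neutral monoisotopic mass of a linear peptide with modifications.

    mods are ``(position, mass_delta)`` pairs, 1-based positions.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = table.water_mass
    for i, residue in enumerate(sequence):
        try:
            total += table.residue_masses[residue]
        except KeyError:
            raise ValueError(
                f"unknown residue code {residue!r} at position {i + 1}"
            ) from None
    for pos, delta in mods:
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"modification position {pos} outside sequence")
        total += delta
    return total


def species_mass(
    species: LinkedSpecies,
    linker: LinkerSpec,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Neutral monoisotopic mass of a cross-linked species.

    inter: m(a) + m(b) + inter residual; loop: m(a) + inter residual;
    mono: m(a) + mono-link residual.  The d6 channel adds the label delta.
    """
    mods_a = [(p, d) for pid, p, d in species.modifications if pid == 0]
    mods_b = [(p, d) for pid, p, d in species.modifications if pid == 1]
    total = peptide_mass(species.peptide_a, mods_a, table)
    if species.link_type is LinkType.INTER:
        total += peptide_mass(species.peptide_b, mods_b, table)
        total += linker.inter_residual_mass_d0
    elif species.link_type is LinkType.LOOP:
        total += linker.inter_residual_mass_d0
    else:
        total += linker.monolink_residual_mass_d0
    if species.channel is Channel.D6:
        total += linker.label_delta
    return total


def mz_from_mass(
    neutral_mass: float, charge: int, table: MassTable = DEFAULT_MASS_TABLE
) -> float:
    """m/z of a neutral mass at the given positive charge state."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * table.proton_mass) / charge


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def composition_mass(formula: str, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Monoisotopic mass of an elemental composition such as ``C7H7NO``."""
    total = 0.0
    consumed = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        element, count = m.group(1), int(m.group(2) or 1)
        if element not in table.element_masses:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        total += table.element_masses[element] * count
        consumed += len(m.group(0))
    if consumed != len(formula):
        raise ValueError(f"unparseable formula {formula!r}")
    return total


def protonated_mz(formula: str, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """m/z of the protonated even-electron cation of ``formula``.

    Computed without electron-mass correction, i.e. as the neutral mass of
    the composition plus one hydrogen atom; this is the convention under
    which the reporter fragment C7H7NO comes out at 122.0606.
    """
    return composition_mass(formula, table) + table.element_masses["H"]


@dataclass(frozen=True)
class Ms2Spectrum:
    """A centroided fragmentation spectrum (peaks sorted by m/z)."""

    scan_id: str
    peaks: tuple[tuple[float, float], ...]
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None

    def __post_init__(self) -> None:
        mzs = [p[0] for p in self.peaks]
        if mzs != sorted(mzs):
            object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))
        if any(p[1] < 0 for p in self.peaks):
            raise ValueError("negative peak intensity")


@dataclass(frozen=True)
class ReporterCheck:
    found: bool
    matched_mz: Optional[float] = None
    relative_intensity: Optional[float] = None


def verify_reporter(
    spectrum: Ms2Spectrum, linker: LinkerSpec, tol_ppm: float = 20.0
) -> ReporterCheck:
    """Check a spectrum for the linker's diagnostic reporter ion.

    Returns the matched peak closest in m/z and its intensity relative to
    the base peak.  An empty peak list simply reports not-found.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if linker.reporter_mz is None:
        raise ValueError(f"linker {linker.name!r} defines no reporter ion")
    if not spectrum.peaks:
        return ReporterCheck(found=False)
    target = linker.reporter_mz
    tol = target * tol_ppm * 1e-6
    candidates = [p for p in spectrum.peaks if abs(p[0] - target) <= tol]
    if not candidates:
        return ReporterCheck(found=False)
    best = min(candidates, key=lambda p: abs(p[0] - target))
    base = max(p[1] for p in spectrum.peaks)
    rel = best[1] / base if base > 0 else 0.0
    return ReporterCheck(found=True, matched_mz=best[0], relative_intensity=rel)
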
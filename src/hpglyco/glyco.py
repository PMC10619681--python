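"""Glycan composition algebra, classification, and diagnostic-ion logic.

N-glycan compositions are described by monosaccharide counts in the
``HexNAc(x)Hex(x)Fuc(x)NeuAc(x)`` notation used throughout site-specific
glycoproteomics: HexNAc is N-acetylhexosamine (GlcNAc/GalNAc), Hex is hexose
(mannose, glucose, galactose), Fuc is fucose (deoxyhexose) and NeuAc is
N-acetylneuraminic (sialic) acid. A composition carries no linkage or isomer
information; it is the unit of glycan identity for quantification.

This module provides:

* parsing/formatting of composition strings (lossless canonical round-trip);
* monoisotopic mass arithmetic over residue masses, including B-type oxonium
  fragment m/z values used as diagnostic ions (e.g. Hex+HexNAc+Fuc at
  m/z 512.20 for core fucose);
* classification into the feature classes driving biomarker aggregation:
  glycan family (high-mannose / complex / hybrid / paucimannose), antennarity,
  a bisecting-GlcNAc heuristic, and fucosylation/sialylation degrees;
* the isobaric-ambiguity search that explains why e.g. Fuc(3)NeuAc(3) and
  Fuc(1)NeuAc(4) variants of the same peptide can be confused: two fucoses
  differ from one sialic acid by only 1.02 Da, within reach of a one-isotope
  monoisotopic-peak misassignment.
"""
from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Sequence

__all__ = [
    "MONOSACCHARIDE_MASSES",
    "PROTON",
    "WATER",
    "ISOTOPE_SPACING",
    "GlycanParseError",
    "GlycanComposition",
    "GlycanClassification",
    "DiagnosticEvidence",
    "AmbiguityGroup",
    "parse_composition",
    "format_composition",
    "composition_mass",
    "oxonium_mz",
    "classify",
    "isobaric_alternatives",
    "diagnostic_ion_check",
]

# Monoisotopic residue masses in Da (residue = monosaccharide minus the
# glycosidic water), immutable at run time.
MONOSACCHARIDE_MASSES = MappingProxyType(
    {
        "HexNAc": 203.07937,
        "Hex": 162.05282,
        "Fuc": 146.05791,
        "NeuAc": 291.09542,
    }
)

PROTON = 1.007276  # Da
WATER = 18.010565  # Da
ISOTOPE_SPACING = 1.003355  # Da, C13-C12

#: Canonical monomer order for formatting.
_MONOMER_ORDER = ("HexNAc", "Hex", "Fuc", "NeuAc")

# sanity of the ambiguity precondition: NeuAc lighter than 2 Fuc
assert MONOSACCHARIDE_MASSES["NeuAc"] < 2 * MONOSACCHARIDE_MASSES["Fuc"]


class GlycanParseError(ValueError):
    """Raised when a composition string cannot be parsed."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide counts of an N-glycan; immutable and hashable."""

    hexnac: int = 0
    hex: int = 0
    fuc: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for name in ("hexnac", "hex", "fuc", "neuac"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise GlycanParseError(
                    f"{name} count must be a non-negative integer, got {v!r}"
                )

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.hexnac, self.hex, self.fuc, self.neuac)

    def is_empty(self) -> bool:
        return not any(self.counts)

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hexnac + other.hexnac,
            self.hex + other.hex,
            self.fuc + other.fuc,
            self.neuac + other.neuac,
        )

    def __str__(self) -> str:
        return format_composition(self)


_TOKEN_RE = re.compile(r"([A-Za-z]+)\((-?\d*\.?\d*)\)")


def parse_composition(text: str) -> GlycanComposition:
    """Parse ``HexNAc(x)Hex(x)Fuc(x)NeuAc(x)`` notation.

    Monomers may appear in any order; omitted monomers count 0. Unknown
    monomer tokens, negative or non-integer counts, and strings that do not
    wholly consist of ``Token(count)`` units raise :class:`GlycanParseError`.
    """
    if not isinstance(text, str) or not text.strip():
        raise GlycanParseError("empty composition string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if text[pos : m.start()].strip():
            raise GlycanParseError(
                f"unparseable fragment {text[pos:m.start()]!r} in {text!r}"
            )
        token, raw = m.group(1), m.group(2)
        if token not in MONOSACCHARIDE_MASSES:
            raise GlycanParseError(f"unknown monomer token {token!r} in {text!r}")
        if not re.fullmatch(r"\d+", raw):
            raise GlycanParseError(
                f"count for {token} must be a non-negative integer, got {raw!r}"
            )
        if token in counts:
            raise GlycanParseError(f"monomer {token} given twice in {text!r}")
        counts[token] = int(raw)
        pos = m.end()
    if pos != len(text) and text[pos:].strip():
        raise GlycanParseError(f"unparseable fragment {text[pos:]!r} in {text!r}")
    if not counts:
        raise GlycanParseError(f"no monomer tokens found in {text!r}")
    return GlycanComposition(
        hexnac=counts.get("HexNAc", 0),
        hex=counts.get("Hex", 0),
        fuc=counts.get("Fuc", 0),
        neuac=counts.get("NeuAc", 0),
    )


def format_composition(comp: GlycanComposition) -> str:
    """Canonical text form: HexNAc, Hex, Fuc, NeuAc order, zeros omitted."""
    attr = {"HexNAc": comp.hexnac, "Hex": comp.hex, "Fuc": comp.fuc, "NeuAc": comp.neuac}
    parts = [f"{name}({attr[name]})" for name in _MONOMER_ORDER if attr[name] > 0]
    if not parts:
        raise GlycanParseError("cannot format the empty composition")
    return "".join(parts)


def composition_mass(comp: GlycanComposition) -> float:
    """Monoisotopic residue-mass sum in Da (0.0 for the empty composition)."""
    return (
        comp.hexnac * MONOSACCHARIDE_MASSES["HexNAc"]
        + comp.hex * MONOSACCHARIDE_MASSES["Hex"]
        + comp.fuc * MONOSACCHARIDE_MASSES["Fuc"]
        + comp.neuac * MONOSACCHARIDE_MASSES["NeuAc"]
    )


def oxonium_mz(fragment: GlycanComposition, water_losses: int = 0) -> float:
    """m/z of a singly protonated B-type oxonium fragment.

    Residue masses already exclude the glycosidic water, so the plain sum plus
    a proton is the B-ion; `water_losses` subtracts additional neutral water
    losses (the common NeuAc-H2O ion at 274.092 uses one loss).
    """
    if fragment.is_empty():
        raise ValueError("oxonium fragment must be non-empty")
    if water_losses < 0:
        raise ValueError("water_losses must be >= 0")
    mz = composition_mass(fragment) - water_losses * WATER + PROTON
    if mz <= 0:
        raise ValueError(f"non-physical oxonium m/z {mz:.4f}")
    return mz


@dataclass(frozen=True)
class GlycanClassification:
    """Derived feature classes of a composition.

    `antennae` is inferred as min(HexNAc-2, Hex-3) for complex glycans (two
    core GlcNAc and three core mannoses are structural); the `bisecting` flag
    fires when HexNAc exceeds what galactosylated antennae can absorb
    (HexNAc-2 > Hex-3). Both are heuristics over compositions, not structures:
    agalactosylated antennae are indistinguishable from a bisecting GlcNAc at
    the composition level, hence `heuristic` is always True for complex calls.
    """

    family: str  # high-mannose | complex | hybrid | paucimannose/other
    antennae: int
    bisecting: bool
    fucosylation_degree: int
    sialylation_degree: int
    heuristic: bool = False

    FAMILIES = ("high-mannose", "complex", "hybrid", "paucimannose/other")


def classify(comp: GlycanComposition) -> GlycanClassification:
    """Total, deterministic classification of a composition.

    high-mannose: HexNAc(2)Hex(5..9), no Fuc/NeuAc (the Man5-Man9 series);
    complex: HexNAc >= 4; hybrid: HexNAc == 3 with Hex >= 5; everything else
    paucimannose/other.
    """
    hn, hx, fc, na = comp.counts
    if hn == 2 and 5 <= hx <= 9 and fc == 0 and na == 0:
        return GlycanClassification("high-mannose", 0, False, 0, 0)
    if hn >= 4:
        antennae = min(hn - 2, hx - 3)
        antennae = max(0, min(antennae, 4))
        bisecting = (hn - 2) > (hx - 3)
        return GlycanClassification("complex", antennae, bisecting, fc, na, heuristic=True)
    if hn == 3 and hx >= 5:
        return GlycanClassification("hybrid", 0, False, fc, na)
    return GlycanClassification("paucimannose/other", 0, False, fc, na)


@dataclass(frozen=True)
class AmbiguityMember:
    composition: GlycanComposition
    mass_delta: float  # Da, candidate minus query
    isotope_error: int  # assumed monoisotopic-peak misassignment, in C13 units


@dataclass(frozen=True)
class AmbiguityGroup:
    query: GlycanComposition
    alternatives: tuple[AmbiguityMember, ...]

    def compositions(self) -> tuple[GlycanComposition, ...]:
        return tuple(m.composition for m in self.alternatives)


def isobaric_alternatives(
    query: GlycanComposition,
    tolerance_ppm: float = 20.0,
    reference_mass: float | None = None,
    isotope_errors: Iterable[int] = (-1, 0, 1),
    search_radius: int = 2,
) -> AmbiguityGroup:
    """Enumerate compositions indistinguishable from `query` by precursor mass.

    Candidates are count perturbations of the query within `search_radius`
    per monomer (which covers the classic 2 Fuc <-> 1 NeuAc swap, mass
    difference 1.02 Da). A candidate is retained when its residue-mass delta
    matches k x 1.003355 Da for some allowed isotope misassignment k, within
    `tolerance_ppm` of `reference_mass` (the intact glycopeptide mass the
    instrument tolerance applies to). The query itself is always a member
    (delta 0, k 0).
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    if reference_mass is None or reference_mass <= 0:
        raise ValueError("reference_mass (Da of the full glycopeptide) must be > 0")
    isotope_errors = sorted(set(int(k) for k in isotope_errors))
    if any(abs(k) > 2 for k in isotope_errors):
        raise ValueError("isotope_errors restricted to {-2..2}")
    tol_da = tolerance_ppm * reference_mass * 1e-6
    qmass = composition_mass(query)
    members = [AmbiguityMember(query, 0.0, 0)]
    deltas = range(-search_radius, search_radius + 1)
    for dh, dx, df, dn in itertools.product(deltas, repeat=4):
        if (dh, dx, df, dn) == (0, 0, 0, 0):
            continue
        cand = (query.hexnac + dh, query.hex + dx, query.fuc + df, query.neuac + dn)
        if any(c < 0 for c in cand) or not any(cand):
            continue
        comp = GlycanComposition(*cand)
        delta = composition_mass(comp) - qmass
        best = None
        for k in isotope_errors:
            err = abs(delta - k * ISOTOPE_SPACING)
            if err <= tol_da and (best is None or err < best[0]):
                best = (err, k)
        if best is not None:
            members.append(AmbiguityMember(comp, delta, best[1]))
    members.sort(key=lambda m: (abs(m.mass_delta), m.composition))
    return AmbiguityGroup(query, tuple(members))


@dataclass(frozen=True)
class PeakMatch:
    label: str
    target_mz: float
    observed_mz: float
    ppm_error: float


@dataclass(frozen=True)
class DiagnosticEvidence:
    """Presence calls for fucose/sialic-acid diagnostic ions in an MS2 scan."""

    core_fucose: bool
    antennary_fucose: bool | None  # None when no peptide mass was supplied
    sialic_acid: bool
    matches: tuple[PeakMatch, ...] = field(default_factory=tuple)


# Diagnostic targets: core fucose oxonium (Hex+HexNAc+Fuc), NeuAc oxonium with
# 0 or 1 water loss.
_CORE_FUC_FRAGMENT = GlycanComposition(hexnac=1, hex=1, fuc=1)
_NEUAC_FRAGMENT = GlycanComposition(neuac=1)


def _match_peaks(
    peaks: Sequence[tuple[float, float]], target: float, tolerance_ppm: float, label: str
) -> list[PeakMatch]:
    out = []
    for mz, _inten in peaks:
        ppm = (mz - target) / target * 1e6
        if abs(ppm) <= tolerance_ppm:
            out.append(PeakMatch(label, target, mz, ppm))
    return out


def diagnostic_ion_check(
    peaks: Sequence[tuple[float, float]],
    tolerance_ppm: float = 20.0,
    peptide_mass: float | None = None,
) -> DiagnosticEvidence:
    """Check an MS2 peak list for fucose and sialic-acid diagnostic ions.

    Core fucose: Hex+HexNAc+Fuc oxonium (m/z 512.20). Sialic acid: NeuAc
    oxonium at 292.10 or its water loss at 274.09. Antennary (outer-arm)
    fucose is a peptide-bearing Y-type ion, peptide+2HexNAc+Fuc+proton, so it
    is only evaluated when the peptide's neutral mass is supplied.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    matches: list[PeakMatch] = []
    matches += _match_peaks(peaks, oxonium_mz(_CORE_FUC_FRAGMENT), tolerance_ppm, "core-fucose")
    core = any(m.label == "core-fucose" for m in matches)
    for losses in (0, 1):
        matches += _match_peaks(
            peaks, oxonium_mz(_NEUAC_FRAGMENT, losses), tolerance_ppm, "sialic-acid"
        )
    sial = any(m.label == "sialic-acid" for m in matches)
    antennary: bool | None = None
    if peptide_mass is not None:
        if peptide_mass <= 0:
            raise ValueError("peptide_mass must be > 0")
        target = (
            peptide_mass
            + 2 * MONOSACCHARIDE_MASSES["HexNAc"]
            + MONOSACCHARIDE_MASSES["Fuc"]
            + PROTON
        )
        matches += _match_peaks(peaks, target, tolerance_ppm, "antennary-fucose")
        antennary = any(m.label == "antennary-fucose" for m in matches)
    return DiagnosticEvidence(core, antennary, sial, tuple(matches))
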
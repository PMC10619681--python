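"""In-silico proteolysis and N-glycosylation sequon discovery.

The target glycoprotein (haptoglobin in the motivating study) is digested
with trypsin plus Glu-C, sequons (N-X-S/T, X != P) are located, and
theoretical glycopeptide m/z values are computed with carbamidomethyl
cysteine as the fixed modification. Coordinates are 0-based half-open
internally; user-facing site labels are 1-based, with a configurable
numbering offset so a mature-chain FASTA can still carry precursor-style
labels such as N184.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from pyteomics import mass as _pmass

from .glyco import PROTON, WATER, GlycanComposition, composition_mass

__all__ = [
    "CANONICAL_AA",
    "CARBAMIDOMETHYL",
    "MET_OXIDATION",
    "TRYPSIN",
    "GLUC_E",
    "GLUC_DE",
    "ProteinRecord",
    "CleavageRule",
    "PeptideSpan",
    "Glycosite",
    "read_fasta",
    "find_sequons",
    "digest",
    "peptide_mass",
    "glycopeptide_mz",
    "map_sites_to_peptides",
]

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
CARBAMIDOMETHYL = 57.02146  # Da, fixed Cys modification
MET_OXIDATION = 15.99491  # Da, optional variable modification

#: Monoisotopic residue masses for the 20 canonical amino acids.
AA_MASSES: Mapping[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in CANONICAL_AA}


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = sorted(set(self.sequence) - CANONICAL_AA)
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains non-canonical residues {bad}"
            )


@dataclass(frozen=True)
class CleavageRule:
    """C-terminal cleavage specificity: cut after `cleave_after` unless the
    next residue is in `blocked_by_next`."""

    name: str
    cleave_after: frozenset[str]
    blocked_by_next: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError(f"rule {self.name!r} has an empty cleave-after set")


TRYPSIN = CleavageRule("trypsin", frozenset("KR"), frozenset("P"))
GLUC_E = CleavageRule("glu-c", frozenset("E"))
# Glu-C also cuts after D in phosphate/bicarbonate buffers; opt-in variant.
GLUC_DE = CleavageRule("glu-c/DE", frozenset("DE"))


@dataclass(frozen=True)
class PeptideSpan:
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    sequence: str
    missed_cleavages: int


@dataclass(frozen=True)
class Glycosite:
    position: int  # 1-based index of the sequon N in the supplied sequence
    sequon: str
    label: str


def read_fasta(path, record_id: str | None = None) -> ProteinRecord:
    """Load one protein from a FASTA file (first record unless `record_id`)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is not None:
        matching = [r for r in records if r.id == record_id or record_id in r.id]
        if not matching:
            raise ValueError(f"record {record_id!r} not found in {path}")
        rec = matching[0]
    else:
        rec = records[0]
    return ProteinRecord(rec.id, str(rec.seq).upper())


_SEQUON_RE = re.compile(r"N(?=[^P][ST])")


def find_sequons(protein: ProteinRecord, numbering_offset: int = 0) -> list[Glycosite]:
    """Locate N-X-S/T sequons (X != P), ordered by position.

    `numbering_offset` is added to the 1-based position in the label only, so
    a mature-chain sequence can be labelled in precursor coordinates.
    """
    sites = []
    for m in _SEQUON_RE.finditer(protein.sequence):
        pos = m.start() + 1
        sites.append(
            Glycosite(pos, protein.sequence[m.start() : m.start() + 3],
                      f"N{pos + numbering_offset}")
        )
    return sites


def _cut_positions(sequence: str, rules: Sequence[CleavageRule]) -> list[int]:
    """0-based positions i such that a cut falls between i and i+1."""
    cuts = set()
    for rule in rules:
        for i in range(len(sequence) - 1):
            if sequence[i] in rule.cleave_after and sequence[i + 1] not in rule.blocked_by_next:
                cuts.add(i)
    return sorted(cuts)


def digest(
    protein: ProteinRecord,
    rules: Sequence[CleavageRule] = (TRYPSIN, GLUC_E),
    max_missed: int = 2,
) -> list[PeptideSpan]:
    """Fully specific digest with up to `max_missed` missed cleavages.

    Cut sites are the union over all rules; every peptide is bounded by cut
    sites (or the protein termini) and contains at most `max_missed` internal
    cut sites. Exhaustive and duplicate-free, ordered by (start, end).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    if not seq:
        return []
    cuts = _cut_positions(seq, rules)
    # boundaries: start indices of fragments
    bounds = [0] + [c + 1 for c in cuts] + [len(seq)]
    spans = []
    for i in range(len(bounds) - 1):
        for m in range(max_missed + 1):
            j = i + m + 1
            if j >= len(bounds):
                break
            s, e = bounds[i], bounds[j]
            spans.append(PeptideSpan(s, e, seq[s:e], m))
    return spans


def peptide_mass(
    sequence: str,
    fixed_cys_mod: float = CARBAMIDOMETHYL,
    oxidized_met: int = 0,
) -> float:
    """Neutral monoisotopic peptide mass with fixed Cys carbamidomethylation."""
    total = WATER
    for i, aa in enumerate(sequence):
        try:
            total += AA_MASSES[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}") from None
    total += sequence.count("C") * fixed_cys_mod
    total += oxidized_met * MET_OXIDATION
    return total


def glycopeptide_mz(
    peptide: PeptideSpan | str,
    glycan: GlycanComposition,
    charge: int,
    fixed_cys_mod: float = CARBAMIDOMETHYL,
) -> float:
    """m/z of a glycopeptide: (peptide + glycan residues + z protons) / z."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    seq = peptide.sequence if isinstance(peptide, PeptideSpan) else peptide
    neutral = peptide_mass(seq, fixed_cys_mod) + composition_mass(glycan)
    return (neutral + charge * PROTON) / charge


@dataclass
class SiteCoverage:
    mapping: dict[int, list[PeptideSpan]] = field(default_factory=dict)
    uncovered: list[Glycosite] = field(default_factory=list)


def map_sites_to_peptides(
    sites: Iterable[Glycosite], peptides: Iterable[PeptideSpan]
) -> SiteCoverage:
    """Map each glycosite to the peptides whose span contains its N."""
    peptides = list(peptides)
    cov = SiteCoverage()
    for site in sites:
        idx = site.position - 1  # 0-based residue index of the N
        hits = [p for p in peptides if p.start <= idx < p.end]
        if hits:
            cov.mapping[site.position] = hits
        else:
            cov.uncovered.append(site)
    return cov
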
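"""Repeat oligonucleotide construction and design arithmetic.

Short tandem pentanucleotide repeats of the WGGGW family (W = A or T), such
as the CANVAS-associated AGGGA motif, are studied as oligonucleotides of
n = 4, 8, 12, 16 repeats.  Because each GGG run can contribute one G-tetrad
layer and four consecutive G>=3 runs can assemble one three-tetrad
G-quadruplex (G4) unit, an n-repeat WGGGW strand carries floor(n/4)
potential intramolecular G4 units.  Keeping the strand concentration at
``base/n`` uM (24/n by default) therefore holds the concentration of
potential G4 units (6 uM) and of potential G-tetrads (18 uM) constant
across n, which makes TDS amplitudes, melting amplitudes and CD intensities
directly comparable between repeat lengths.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from enum import Enum

from .errors import AlphabetError, DomainError

_DNA_ALPHABET = frozenset("ACGT")
_RNA_ALPHABET = frozenset("ACGU")


class NucleicAcid(str, Enum):
    DNA = "DNA"
    RNA = "RNA"


class Species(str, Enum):
    """Folded species whose apparent size the gel-mobility reasoning uses."""

    INTRAMOLECULAR_G4 = "intramolecular_G4"
    BIMOLECULAR_DUPLEX = "bimolecular_duplex"
    INTRAMOLECULAR_HAIRPIN = "intramolecular_hairpin"


@dataclass(frozen=True)
class RepeatSequence:
    """A motif of length 5 (or 6 for control hexanucleotides) repeated n times."""

    motif: str
    n_repeats: int
    nucleic_acid: NucleicAcid = NucleicAcid.DNA

    def __post_init__(self) -> None:
        if len(self.motif) not in (5, 6):
            raise DomainError(f"motif length must be 5 or 6, got {len(self.motif)}")
        if self.n_repeats < 1:
            raise DomainError(f"n_repeats must be >= 1, got {self.n_repeats}")
        alphabet = _DNA_ALPHABET if self.nucleic_acid is NucleicAcid.DNA else _RNA_ALPHABET
        bad = set(self.motif) - alphabet
        if bad:
            raise AlphabetError(
                f"motif {self.motif!r} contains {sorted(bad)} not in the "
                f"{self.nucleic_acid.value} alphabet {sorted(alphabet)}"
            )

    @property
    def sequence(self) -> str:
        return self.motif * self.n_repeats

    def __len__(self) -> int:
        return len(self.motif) * self.n_repeats

    @property
    def name(self) -> str:
        return f"{self.motif}_x{self.n_repeats}"

    def to_fasta(self) -> str:
        """Single-record FASTA, ID ``MOTIF_xN``, 60-column wrapping."""
        seq = self.sequence
        lines = [seq[i : i + 60] for i in range(0, len(seq), 60)]
        return ">" + self.name + "\n" + "\n".join(lines) + "\n"


@dataclass(frozen=True)
class DesignSummary:
    """Design arithmetic for one repeat oligonucleotide at one strand concentration.

    ``tetrad_conc_uM`` is three times the G4-unit concentration: a G4 unit
    built from GGG runs stacks exactly three G-tetrads.
    """

    g3_run_count: int
    potential_g4_units: int
    strand_conc_uM: float
    unit_conc_uM: float
    tetrad_conc_uM: float


def build_repeat(
    motif: str, n: int, nucleic_acid: NucleicAcid | str = NucleicAcid.DNA
) -> RepeatSequence:
    """Construct a validated :class:`RepeatSequence` from motif and repeat count."""
    if not motif:
        raise DomainError("motif must be nonempty")
    return RepeatSequence(motif.upper(), n, NucleicAcid(nucleic_acid))


def count_g_runs(seq: RepeatSequence | str, min_len: int = 3) -> int:
    """Number of maximal runs of consecutive G of length >= ``min_len``.

    Runs are maximal (bounded by non-G or sequence ends), so they are
    non-overlapping by construction.  G-run length is the discriminant for
    G4-forming potential: motifs with only GG runs (e.g. AGGAC) have zero
    G3 runs and no canonical three-tetrad G4 potential.
    """
    if min_len < 1:
        raise DomainError(f"min_len must be >= 1, got {min_len}")
    s = seq.sequence if isinstance(seq, RepeatSequence) else seq
    return sum(1 for m in re.finditer(r"G+", s) if len(m.group()) >= min_len)


def design_summary(seq: RepeatSequence, strand_conc_uM: float) -> DesignSummary:
    """Potential G4 units and unit/tetrad concentrations at a strand concentration.

    Four consecutive G>=3 runs form one potential G4 unit (left-to-right,
    greedy), so a strand with g G3 runs holds floor(g/4) units; the unit
    concentration is that count times the strand concentration and the
    tetrad concentration is three tetrads per unit.
    """
    if strand_conc_uM <= 0:
        raise DomainError(f"strand concentration must be > 0, got {strand_conc_uM}")
    g3 = count_g_runs(seq, min_len=3)
    units = g3 // 4
    unit_conc = units * strand_conc_uM
    return DesignSummary(
        g3_run_count=g3,
        potential_g4_units=units,
        strand_conc_uM=strand_conc_uM,
        unit_conc_uM=unit_conc,
        tetrad_conc_uM=3.0 * unit_conc,
    )


def design_strand_concentration(n: int, base_uM: float = 24.0) -> float:
    """Strand concentration base/n uM that equalizes potential-G4-unit concentration.

    With the default base of 24 uM this is 6, 3, 2 and 1.5 uM for
    n = 4, 8, 12, 16 repeats.
    """
    if n <= 0:
        raise DomainError(f"repeat count must be positive, got {n}")
    if base_uM <= 0:
        raise DomainError(f"base concentration must be positive, got {base_uM}")
    return base_uM / n


def predicted_species_size(seq: RepeatSequence, species: Species | str) -> int:
    """Apparent size of a candidate folded species, in bp (duplexes) or nt (G4).

    A full-register two-strand duplex of an n-repeat strand runs as
    n x motif-length bp (e.g. 40/60/80 bp for 8/12/16 pentanucleotide
    repeats); an intramolecular hairpin pairs half the strand with itself;
    an intramolecular G4 involves the full strand length in nt.
    """
    species = Species(species)
    total = len(seq)
    if species is Species.BIMOLECULAR_DUPLEX:
        return total
    if species is Species.INTRAMOLECULAR_HAIRPIN:
        return math.floor(total / 2)
    return total  # intramolecular G4, nt
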
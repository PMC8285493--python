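"""Nucleotide and protein primitives shared by every pipeline stage.

Coordinates are 0-based half-open on nucleotides internally; codon numbers
are 1-based and equal to protein residue numbers in all user-facing output
(an ``ORFSequence`` carries a ``codon_offset`` so a sub-ORF such as the
PDE3A catalytic region can number its first codon 668).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CODON_TABLE",
    "SENSE_CODONS",
    "STOP_CODONS",
    "ORFSequence",
    "RestrictionSite",
    "GuideMatch",
    "reverse_complement",
    "translate",
    "translate_dna",
    "average_protein_mass",
    "find_restriction_sites",
    "find_guide_matches",
    "read_fasta",
    "write_fasta",
]

_DNA_RE = re.compile(r"^[ACGT]+$")


def _build_codon_table() -> dict[str, str]:
    std = unambiguous_dna_by_id[1]
    table = dict(std.forward_table)
    for stop in std.stop_codons:
        table[stop] = "*"
    return table


#: Standard genetic code: all 64 codons -> one-letter amino acid or '*'.
CODON_TABLE: dict[str, str] = _build_codon_table()
STOP_CODONS: frozenset[str] = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS: frozenset[str] = frozenset(c for c, aa in CODON_TABLE.items() if aa != "*")

#: Codons encoding each amino acid (and '*'), sorted alphabetically.
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon in sorted(CODON_TABLE):
    CODONS_FOR_AA.setdefault(CODON_TABLE[_codon], tuple())
    CODONS_FOR_AA[CODON_TABLE[_codon]] += (_codon,)

# Isotope-averaged residue masses (Da), i.e. the amino acid minus one water,
# as used for "theoretical mass" comparisons against SEC-MALS.
RESIDUE_AVERAGE_MASS: dict[str, float] = {
    "A": 71.0788,
    "R": 156.1875,
    "N": 114.1038,
    "D": 115.0886,
    "C": 103.1388,
    "E": 129.1155,
    "Q": 128.1307,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "L": 113.1594,
    "K": 128.1741,
    "M": 131.1926,
    "F": 147.1766,
    "P": 97.1167,
    "S": 87.0782,
    "T": 101.1051,
    "W": 186.2132,
    "Y": 163.1760,
    "V": 99.1326,
}
WATER_AVERAGE_MASS = 18.0153

IUPAC_DNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(dna: str) -> str:
    """Reverse complement of a strict-ACGT sequence."""
    _check_dna(dna)
    return dna.translate(_COMPLEMENT)[::-1]


def _check_dna(dna: str) -> None:
    if not _DNA_RE.match(dna):
        bad = sorted(set(dna) - set("ACGT"))
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")


@dataclass(frozen=True)
class ORFSequence:
    """An open reading frame with codon numbering tied to residue numbers.

    Parameters
    ----------
    id : str
        Label for the sequence.
    nucleotides : str
        Upper-case DNA over {A, C, G, T}; length divisible by 3.
    codon_offset : int
        Codon number assigned to the first codon, so codon numbers match
        protein residue numbers (668 for a catalytic-region sub-ORF that
        starts at residue 668, 1 for a full ORF).
    """

    id: str
    nucleotides: str
    codon_offset: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "nucleotides", self.nucleotides.upper())
        _check_dna(self.nucleotides)
        if len(self.nucleotides) % 3 != 0:
            raise ValueError(
                f"ORF length {len(self.nucleotides)} not divisible by 3"
            )

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    @property
    def first_codon(self) -> int:
        return self.codon_offset

    @property
    def last_codon(self) -> int:
        return self.codon_offset + self.n_codons - 1

    def codon(self, codon_number: int) -> str:
        """The codon (triplet) at a 1-based codon/residue number."""
        i = self._codon_index(codon_number)
        return self.nucleotides[3 * i : 3 * i + 3]

    def codon_numbers(self) -> Iterator[int]:
        return iter(range(self.first_codon, self.last_codon + 1))

    def _codon_index(self, codon_number: int) -> int:
        i = codon_number - self.codon_offset
        if not 0 <= i < self.n_codons:
            raise IndexError(
                f"codon {codon_number} outside ORF range "
                f"{self.first_codon}..{self.last_codon}"
            )
        return i

    def with_codon(self, codon_number: int, new_codon: str) -> "ORFSequence":
        """A copy with one codon substituted."""
        _check_dna(new_codon)
        if len(new_codon) != 3:
            raise ValueError("codon must be a triplet")
        i = self._codon_index(codon_number)
        nt = self.nucleotides
        return ORFSequence(
            self.id, nt[: 3 * i] + new_codon + nt[3 * i + 3 :], self.codon_offset
        )


@dataclass(frozen=True)
class RestrictionSite:
    """A named recognition sequence, possibly IUPAC-degenerate."""

    name: str
    recognition: str

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        if len(rec) < 4:
            raise ValueError(f"recognition sequence too short: {rec!r}")
        bad = set(rec) - set(IUPAC_DNA)
        if bad:
            raise ValueError(f"invalid IUPAC codes in {rec!r}: {sorted(bad)}")


NHEI = RestrictionSite("NheI", "GCTAGC")
BAMHI = RestrictionSite("BamHI", "GGATCC")


@dataclass(frozen=True)
class GuideMatch:
    """A guide-RNA target site resolved to + strand coordinates."""

    start: int
    strand: str
    protospacer: str
    pam: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def end(self) -> int:
        """End of the protospacer+PAM footprint on the + strand (exclusive)."""
        return self.start + len(self.protospacer) + len(self.pam)


def translate(orf: ORFSequence) -> str:
    """Translate an ORF with the standard genetic code ('*' for stop)."""
    return translate_dna(orf.nucleotides)


def translate_dna(dna: str) -> str:
    """Translate a raw in-frame DNA string."""
    _check_dna(dna)
    if len(dna) % 3 != 0:
        raise ValueError(f"length {len(dna)} not divisible by 3")
    return str(Seq(dna).translate())


def average_protein_mass(protein: str, unit: str = "Da") -> float:
    """Isotope-averaged mass of a protein: sum of residue masses plus one water.

    Parameters
    ----------
    protein : str
        One-letter codes over the 20 standard amino acids (no ``*``).
    unit : {"Da", "kDa"}
    """
    if not protein:
        raise ValueError("empty protein sequence")
    try:
        mass = sum(RESIDUE_AVERAGE_MASS[aa] for aa in protein) + WATER_AVERAGE_MASS
    except KeyError as exc:
        raise ValueError(f"unknown residue code: {exc.args[0]!r}") from None
    if unit == "Da":
        return mass
    if unit == "kDa":
        return mass / 1000.0
    raise ValueError(f"unknown unit {unit!r}")


def _iupac_regex(pattern: str) -> re.Pattern[str]:
    parts = []
    for code in pattern.upper():
        bases = IUPAC_DNA[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def find_restriction_sites(dna: str, site: RestrictionSite) -> list[int]:
    """All 0-based start offsets of a recognition site (degeneracy-aware).

    Overlapping matches are all reported; the list is sorted ascending.
    """
    _check_dna(dna)
    rx = _iupac_regex(site.recognition)
    # lookahead so overlapping occurrences are not swallowed
    return [m.start() for m in re.finditer(f"(?={rx.pattern})", dna)]


def find_guide_matches(
    dna: str, guide: str, pam_pattern: str = "NGG"
) -> list[GuideMatch]:
    """Cas9 target sites for ``guide`` on both strands of ``dna``.

    A match requires guide identity immediately 5' of a PAM-pattern hit.
    Coordinates are reported on the + strand: ``start`` is the leftmost
    nucleotide of the protospacer+PAM footprint regardless of strand.
    """
    guide = guide.upper()
    _check_dna(guide)
    if len(guide) < 15:
        raise ValueError(f"guide too short ({len(guide)} nt, need >= 15)")
    _check_dna(dna)
    pam_rx = _iupac_regex(pam_pattern)
    g, p = len(guide), len(pam_pattern)
    matches: list[GuideMatch] = []
    # + strand: guide then PAM
    for i in range(len(dna) - g - p + 1):
        if dna[i : i + g] == guide and pam_rx.fullmatch(dna[i + g : i + g + p]):
            matches.append(GuideMatch(i, "+", dna[i : i + g], dna[i + g : i + g + p]))
    # - strand: revcomp(PAM) then revcomp(guide) in + coordinates
    rc_guide = reverse_complement(guide)
    for i in range(len(dna) - g - p + 1):
        if dna[i + p : i + p + g] == rc_guide and pam_rx.fullmatch(
            reverse_complement(dna[i : i + p])
        ):
            matches.append(
                GuideMatch(i, "-", dna[i + p : i + p + g], dna[i : i + p])
            )
    matches.sort(key=lambda m: (m.start, m.strand))
    return matches


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file, sequences upper-cased."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as upper-case FASTA wrapped at 60 columns."""
    recs = [
        SeqRecord(Seq(seq.upper()), id=str(name), description="")
        for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(recs)
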
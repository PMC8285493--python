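"""Codon-saturation library design and synonymous PAM-site recoding.

The design walks every codon of a target region and, for each of the 20
non-wild-type targets (19 missense + 1 nonsense), picks a single alternative
codon.  Candidate codons are ranked to *maximize* nucleotide distance from
the wild-type codon (single-nucleotide neighbours are used only as a last
resort, so that sequencing errors are not mistaken for designed variants),
with ties broken by human codon-usage frequency and then alphabetically.
Candidates that would create a forbidden restriction site are rejected; a
target amino acid with no surviving candidate is recorded as dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .sequence_core import (
    BAMHI,
    CODON_TABLE,
    CODONS_FOR_AA,
    NHEI,
    ORFSequence,
    RestrictionSite,
    find_guide_matches,
    find_restriction_sites,
    translate,
    write_fasta,
)

__all__ = [
    "DesignConstraints",
    "VariantSpec",
    "LibraryDesign",
    "RecodedORF",
    "design_saturation_library",
    "recode_pam_sites",
    "write_library",
    "read_library",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Human codon usage, frequency per thousand (GenBank aggregate table).
# Used only as a deterministic tie-break after the codon-distance criterion.
HUMAN_CODON_USAGE: dict[str, float] = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3, "TAA": 1.0, "TAG": 0.8,
    "CAT": 10.9, "CAC": 15.1, "CAA": 12.3, "CAG": 34.2,
    "AAT": 17.0, "AAC": 19.1, "AAA": 24.4, "AAG": 31.9,
    "GAT": 21.8, "GAC": 25.1, "GAA": 29.0, "GAG": 39.6,
    "TGT": 10.6, "TGC": 12.6, "TGA": 1.6, "TGG": 13.2,
    "CGT": 4.5, "CGC": 10.4, "CGA": 6.2, "CGG": 11.4,
    "AGT": 12.1, "AGC": 19.5, "AGA": 12.2, "AGG": 12.0,
    "GGT": 10.8, "GGC": 22.2, "GGA": 16.5, "GGG": 16.5,
}


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class DesignConstraints:
    """Region bounds and constraints for a saturation design.

    region_start/region_end are inclusive codon (= residue) numbers.
    """

    region_start: int
    region_end: int
    forbidden_sites: tuple[RestrictionSite, ...] = (NHEI, BAMHI)
    silent_count: int = 0

    def __post_init__(self) -> None:
        if self.region_start > self.region_end:
            raise ValueError("region_start > region_end")
        if self.silent_count < 0:
            raise ValueError("silent_count must be non-negative")
        object.__setattr__(self, "forbidden_sites", tuple(self.forbidden_sites))


@dataclass(frozen=True)
class VariantSpec:
    """One designed codon substitution."""

    variant_id: str
    codon_number: int
    wt_codon: str
    alt_codon: str
    wt_aa: str
    alt_aa: str
    var_class: str  # missense | nonsense | silent
    nt_distance: int

    def __post_init__(self) -> None:
        if self.alt_codon == self.wt_codon:
            raise ValueError("alt_codon equals wt_codon")
        if CODON_TABLE[self.wt_codon] != self.wt_aa:
            raise ValueError("wt_aa inconsistent with wt_codon")
        if CODON_TABLE[self.alt_codon] != self.alt_aa:
            raise ValueError("alt_aa inconsistent with alt_codon")
        expected = (
            "nonsense"
            if self.alt_aa == "*"
            else ("silent" if self.alt_aa == self.wt_aa else "missense")
        )
        if self.var_class != expected:
            raise ValueError(
                f"var_class {self.var_class!r} inconsistent, expected {expected!r}"
            )
        if self.nt_distance != hamming(self.wt_codon, self.alt_codon):
            raise ValueError("nt_distance inconsistent with codons")


@dataclass
class LibraryDesign:
    """A designed variant library over a reference ORF."""

    reference: ORFSequence
    variants: list[VariantSpec] = field(default_factory=list)
    dropped: list[tuple[int, str, str]] = field(default_factory=list)

    def variant_sequence(self, spec: VariantSpec) -> str:
        """Full-length nucleotide sequence of one variant."""
        return self.reference.with_codon(spec.codon_number, spec.alt_codon).nucleotides

    def by_id(self) -> dict[str, VariantSpec]:
        return {v.variant_id: v for v in self.variants}

    def alt_index(self) -> dict[tuple[int, str], str]:
        """(codon_number, alt_codon) -> variant_id lookup, cached."""
        cached = self.__dict__.get("_alt_index")
        if cached is None or len(cached) != len(self.variants):
            cached = {(v.codon_number, v.alt_codon): v.variant_id for v in self.variants}
            self.__dict__["_alt_index"] = cached
        return cached

    @property
    def non_silent(self) -> list[VariantSpec]:
        return [v for v in self.variants if v.var_class != "silent"]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LibraryDesign)
            and self.reference == other.reference
            and sorted(self.variants, key=_sort_key) == sorted(other.variants, key=_sort_key)
        )


def _sort_key(v: VariantSpec):
    return (v.codon_number, v.alt_aa, v.alt_codon)


def _ranked_candidates(wt_codon: str, target_aa: str) -> list[str]:
    """Candidate codons for a target amino acid, best first."""
    cands = [c for c in CODONS_FOR_AA[target_aa] if c != wt_codon]
    return sorted(
        cands,
        key=lambda c: (-hamming(wt_codon, c), -HUMAN_CODON_USAGE[c], c),
    )


def _creates_forbidden_site(
    orf: ORFSequence,
    codon_number: int,
    alt_codon: str,
    sites: tuple[RestrictionSite, ...],
) -> bool:
    """Window check: would this codon edit create any forbidden site?

    Only sites overlapping the edited codon can appear, so scanning the
    codon +/- (longest site length - 1) nucleotides is sufficient.
    """
    if not sites:
        return False
    nt = orf.nucleotides
    i = (codon_number - orf.codon_offset) * 3
    pad = max(len(s.recognition) for s in sites) - 1
    lo, hi = max(0, i - pad), min(len(nt), i + 3 + pad)
    window = nt[lo:i] + alt_codon + nt[i + 3 : hi]
    return any(find_restriction_sites(window, s) for s in sites)


def _variant_id(wt_aa: str, codon_number: int, alt_aa: str) -> str:
    return f"{wt_aa}{codon_number}{alt_aa}"


def design_saturation_library(
    orf: ORFSequence, constraints: DesignConstraints
) -> LibraryDesign:
    """Design the codon-saturation library for a region of an ORF.

    For every codon in the region, one variant (or a dropped record) is
    produced per target in {20 standard amino acids + stop} minus the
    wild-type amino acid; ``silent_count`` synonymous variants are then
    placed at evenly spaced positions.  The result is a pure function of
    the inputs.
    """
    if orf.first_codon > constraints.region_start or orf.last_codon < constraints.region_end:
        raise ValueError(
            f"region {constraints.region_start}..{constraints.region_end} outside "
            f"ORF {orf.first_codon}..{orf.last_codon}"
        )
    protein = translate(orf)
    if "*" in protein[:-1]:
        raise ValueError("reference ORF has an internal stop codon")
    for site in constraints.forbidden_sites:
        hits = find_restriction_sites(orf.nucleotides, site)
        if hits:
            raise ValueError(
                f"reference ORF already contains forbidden site {site.name} at {hits}"
            )

    design = LibraryDesign(reference=orf)
    region = range(constraints.region_start, constraints.region_end + 1)

    for codon_number in region:
        wt_codon = orf.codon(codon_number)
        wt_aa = CODON_TABLE[wt_codon]
        targets = [aa for aa in AA20 if aa != wt_aa] + ["*"]
        for target_aa in targets:
            chosen = None
            for cand in _ranked_candidates(wt_codon, target_aa):
                if not _creates_forbidden_site(
                    orf, codon_number, cand, constraints.forbidden_sites
                ):
                    chosen = cand
                    break
            if chosen is None:
                design.dropped.append((codon_number, target_aa, "restriction_site"))
                continue
            design.variants.append(
                VariantSpec(
                    variant_id=_variant_id(wt_aa, codon_number, target_aa),
                    codon_number=codon_number,
                    wt_codon=wt_codon,
                    alt_codon=chosen,
                    wt_aa=wt_aa,
                    alt_aa=target_aa,
                    var_class="nonsense" if target_aa == "*" else "missense",
                    nt_distance=hamming(wt_codon, chosen),
                )
            )

    _place_silent_variants(design, orf, constraints)
    design.variants.sort(key=_sort_key)
    return design


def _silent_candidate(
    orf: ORFSequence, codon_number: int, sites: tuple[RestrictionSite, ...]
) -> str | None:
    wt_codon = orf.codon(codon_number)
    wt_aa = CODON_TABLE[wt_codon]
    for cand in _ranked_candidates(wt_codon, wt_aa):
        if not _creates_forbidden_site(orf, codon_number, cand, sites):
            return cand
    return None


def _place_silent_variants(
    design: LibraryDesign, orf: ORFSequence, constraints: DesignConstraints
) -> None:
    k = constraints.silent_count
    if k == 0:
        return
    lo, hi = constraints.region_start, constraints.region_end
    n = hi - lo + 1
    eligible = [
        c for c in range(lo, hi + 1)
        if _silent_candidate(orf, c, constraints.forbidden_sites) is not None
    ]
    if k > len(eligible):
        raise ValueError(
            f"silent_count {k} exceeds the {len(eligible)} region positions "
            "with a usable synonymous alternative"
        )
    used: set[int] = set()
    for j in range(k):
        # even spacing by codon index; skip forward past Met/Trp and
        # already-used positions
        target = lo + (j * n) // k
        pos = target
        while True:
            if pos > hi:
                pos = lo  # wrap: remaining slots fill from the region start
            if pos not in used:
                cand = _silent_candidate(orf, pos, constraints.forbidden_sites)
                if cand is not None:
                    break
            pos += 1
        used.add(pos)
        wt_codon = orf.codon(pos)
        wt_aa = CODON_TABLE[wt_codon]
        design.variants.append(
            VariantSpec(
                variant_id=_variant_id(wt_aa, pos, wt_aa),
                codon_number=pos,
                wt_codon=wt_codon,
                alt_codon=cand,
                wt_aa=wt_aa,
                alt_aa=wt_aa,
                var_class="silent",
                nt_distance=hamming(wt_codon, cand),
            )
        )


@dataclass
class RecodedORF:
    """An ORF with synonymous edits removing guide-RNA target sites."""

    orf: ORFSequence
    edits: list[tuple[int, str, str]] = field(default_factory=list)


def recode_pam_sites(
    orf: ORFSequence, guide: str, pam_pattern: str = "NGG"
) -> RecodedORF:
    """Synonymously recode an ORF so a Cas9 guide no longer matches it.

    One synonymous codon change is made per guide match, chosen within the
    protospacer/PAM footprint and preferring the PAM-proximal (seed) codon.
    Translation is unchanged; a match whose footprint offers no synonymous
    escape raises ``ValueError``.
    """
    current = orf
    edits: list[tuple[int, str, str]] = []
    protein = translate(orf)
    guard = 0
    while True:
        matches = find_guide_matches(current.nucleotides, guide, pam_pattern)
        if not matches:
            break
        guard += 1
        if guard > 100:
            raise RuntimeError("recoding did not converge")
        m = matches[0]
        first = max(current.first_codon, current.codon_offset + m.start // 3)
        last = min(current.last_codon, current.codon_offset + (m.end - 1) // 3)
        footprint = list(range(first, last + 1))
        # seed (PAM-proximal) end: right end for + strand, left for -
        footprint.sort(key=lambda c: (last - c) if m.strand == "+" else (c - first))
        fixed = None
        for codon_number in footprint:
            wt_codon = current.codon(codon_number)
            wt_aa = CODON_TABLE[wt_codon]
            for cand in _ranked_candidates(wt_codon, wt_aa):
                trial = current.with_codon(codon_number, cand)
                if len(find_guide_matches(trial.nucleotides, guide, pam_pattern)) < len(
                    matches
                ):
                    fixed = (codon_number, wt_codon, cand)
                    current = trial
                    break
            if fixed:
                break
        if fixed is None:
            raise ValueError(
                f"guide match at {m.start} ({m.strand}) cannot be removed by a "
                "synonymous edit (no synonymous alternative in its footprint)"
            )
        edits.append(fixed)
    assert translate(current) == protein
    return RecodedORF(orf=current, edits=edits)


LIBRARY_COLUMNS = [
    "variant_id",
    "codon_number",
    "wt_codon",
    "alt_codon",
    "wt_aa",
    "alt_aa",
    "var_class",
    "nt_distance",
]


def library_table(design: LibraryDesign) -> pd.DataFrame:
    """The design as a table, one row per variant, deterministic order."""
    rows = [
        {c: getattr(v, c) for c in LIBRARY_COLUMNS}
        for v in sorted(design.variants, key=_sort_key)
    ]
    return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


def write_library(design: LibraryDesign, table_path, fasta_path=None) -> None:
    """Write the variant table (TSV) and optionally full-length variant FASTA."""
    library_table(design).to_csv(table_path, sep="\t", index=False)
    if fasta_path is not None:
        records = [
            (v.variant_id, design.variant_sequence(v))
            for v in sorted(design.variants, key=_sort_key)
        ]
        write_fasta(records, fasta_path)


def read_library(table_path, reference: ORFSequence) -> LibraryDesign:
    """Reconstruct a LibraryDesign from a variant table and its reference."""
    df = pd.read_csv(
        table_path, sep="\t", dtype={c: str for c in LIBRARY_COLUMNS}
    )
    variants = [
        VariantSpec(
            variant_id=row.variant_id,
            codon_number=int(row.codon_number),
            wt_codon=row.wt_codon,
            alt_codon=row.alt_codon,
            wt_aa=row.wt_aa,
            alt_aa=row.alt_aa,
            var_class=row.var_class,
            nt_distance=int(row.nt_distance),
        )
        for row in df.itertuples()
    ]
    return LibraryDesign(reference=reference, variants=variants)
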
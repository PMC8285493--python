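"""Structural classification of resistance-hit residues.

Hit residues are assigned to one of three mechanistic categories — the
catalytic (active) site, the homodimerization interface, or the SLFN12
binding site — either from explicit residue-number sets or derived from a
coordinate file by heavy-atom distance cutoffs (receptor residues near the
bound ligand, near the sister receptor chain, or near a partner chain).
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "RegionDefinition",
    "DerivationParams",
    "classify_hits",
    "derive_regions",
]

CATEGORY_PRIORITY = ("active_site", "dimer_interface", "slfn12_interface")


@dataclass(frozen=True)
class RegionDefinition:
    """Named residue-number sets; sets may overlap."""

    active_site: frozenset[int] = frozenset()
    dimer_interface: frozenset[int] = frozenset()
    slfn12_interface: frozenset[int] = frozenset()
    excluded_fold_set: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        for name in ("active_site", "dimer_interface", "slfn12_interface",
                     "excluded_fold_set"):
            object.__setattr__(self, name, frozenset(getattr(self, name)))

    @classmethod
    def from_dict(cls, d: dict) -> "RegionDefinition":
        return cls(
            active_site=frozenset(d.get("active_site", ())),
            dimer_interface=frozenset(d.get("dimer_interface", ())),
            slfn12_interface=frozenset(d.get("slfn12_interface", ())),
            excluded_fold_set=frozenset(d.get("excluded_fold_set", ())),
        )


@dataclass(frozen=True)
class DerivationParams:
    """How to derive residue sets from a structure."""

    structure_path: str
    ligand_name: str
    receptor_chains: tuple[str, ...]
    partner_chains: tuple[str, ...] = ()
    cutoff: float = 4.5  # heavy-atom distance, Angstrom

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        object.__setattr__(self, "receptor_chains", tuple(self.receptor_chains))
        object.__setattr__(self, "partner_chains", tuple(self.partner_chains))


def classify_hits(
    score_table: pd.DataFrame, regions: RegionDefinition
) -> pd.DataFrame:
    """Aggregate resistance-hit variants by residue and classify each residue.

    A residue is a hit residue if any variant at that codon is flagged; its
    category is the first matching set in priority order active_site >
    dimer_interface > slfn12_interface, else 'unassigned'.  Residues in the
    excluded fold set are removed before classification.
    """
    if "codon_number" not in score_table.columns:
        raise ValueError("score table lacks codon_number; score with a design")
    flags = score_table["resistance_hit"]
    hits = score_table[flags.notna() & (flags == True)]  # noqa: E712 (nullable bool)
    rows = []
    for residue, group in hits.groupby("codon_number"):
        residue = int(residue)
        if residue in regions.excluded_fold_set:
            continue
        category = "unassigned"
        for name in CATEGORY_PRIORITY:
            if residue in getattr(regions, name):
                category = name
                break
        rows.append(
            {
                "residue": residue,
                "category": category,
                "variant_ids": ",".join(sorted(group.index)),
                "n_variants": len(group),
            }
        )
    return pd.DataFrame(
        rows, columns=["residue", "category", "variant_ids", "n_variants"]
    ).set_index("residue")


def _heavy_atoms(structure: gemmi.Structure):
    """(chain, residue_number, residue_name, xyz) for every non-hydrogen atom
    of the first model."""
    model = structure[0]
    out = []
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                out.append(
                    (
                        chain.name,
                        res.seqid.num,
                        res.name,
                        (atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                )
    return out


def _near_residues(
    query_xyz: np.ndarray,
    receptor_xyz: np.ndarray,
    receptor_resnum: np.ndarray,
    cutoff: float,
) -> frozenset[int]:
    if len(query_xyz) == 0 or len(receptor_xyz) == 0:
        return frozenset()
    tree = cKDTree(query_xyz)
    dist, _ = tree.query(receptor_xyz, k=1, distance_upper_bound=cutoff)
    return frozenset(int(r) for r in receptor_resnum[np.isfinite(dist)])


def derive_regions(params: DerivationParams) -> RegionDefinition:
    """Derive the three residue sets from a structure by distance cutoffs.

    active_site: receptor residues with any heavy atom within ``cutoff`` of
    any ligand heavy atom; dimer_interface: receptor residues near a *different*
    receptor chain; slfn12_interface: receptor residues near any partner
    chain.  Results are unions over all receptor chains.
    """
    structure = gemmi.read_structure(str(params.structure_path))
    structure.setup_entities()
    atoms = _heavy_atoms(structure)
    chains = {a[0] for a in atoms}
    missing = set(params.receptor_chains) - chains
    if missing:
        raise ValueError(f"receptor chains not in structure: {sorted(missing)}")
    missing = set(params.partner_chains) - chains
    if missing:
        raise ValueError(f"partner chains not in structure: {sorted(missing)}")

    ligand_xyz = np.array(
        [a[3] for a in atoms if a[2] == params.ligand_name], dtype=float
    )
    if params.ligand_name and len(ligand_xyz) == 0:
        raise ValueError(f"ligand {params.ligand_name!r} not found in structure")
    partner_xyz = np.array(
        [a[3] for a in atoms if a[0] in params.partner_chains], dtype=float
    )

    active, dimer, slfn = set(), set(), set()
    for rc in params.receptor_chains:
        rec = [
            a for a in atoms
            if a[0] == rc and a[2] != params.ligand_name and not _is_water(a[2])
        ]
        rec_xyz = np.array([a[3] for a in rec], dtype=float)
        rec_num = np.array([a[1] for a in rec], dtype=int)
        if len(ligand_xyz):
            active |= _near_residues(ligand_xyz, rec_xyz, rec_num, params.cutoff)
        other_xyz = np.array(
            [
                a[3] for a in atoms
                if a[0] in params.receptor_chains and a[0] != rc
                and a[2] != params.ligand_name and not _is_water(a[2])
            ],
            dtype=float,
        )
        if len(other_xyz):
            dimer |= _near_residues(other_xyz, rec_xyz, rec_num, params.cutoff)
        if len(partner_xyz):
            slfn |= _near_residues(partner_xyz, rec_xyz, rec_num, params.cutoff)

    return RegionDefinition(
        active_site=frozenset(active),
        dimer_interface=frozenset(dimer),
        slfn12_interface=frozenset(slfn),
    )


def _is_water(resname: str) -> bool:
    return resname in ("HOH", "WAT", "DOD")
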
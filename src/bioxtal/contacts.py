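"""Intermolecular residue-residue contacts and their physico-chemical bookkeeping.

A residue contact (RC) is a pair of residues, one per interface partner,
with at least one heavy-atom pair strictly closer than the distance cutoff
(default 5.0 A).  Contacts are binned by the charged/polar/apolar character
of the two residues (six class pairs: CC, CP, CA, PP, PA, AA) and counted
per amino-acid type; the link density LD = RCs / (Res1 * Res2) measures how
densely the interface network is wired, where Res1 and Res2 count the
residues on each side that take part in at least one contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import InterfacePair, Residue

__all__ = [
    "RESIDUE_CLASS",
    "CLASS_PAIRS",
    "Contact",
    "ContactProfile",
    "classify_residue",
    "compute_contacts",
    "summarize_contacts",
    "contact_table",
]

# charged/polar/apolar assignment of the twenty standard residues:
# N, Q, S, T polar; E, D, H, K, R charged; the rest apolar.
_POLAR = {"ASN", "GLN", "SER", "THR"}
_CHARGED = {"GLU", "ASP", "HIS", "LYS", "ARG"}
_APOLAR = {"ALA", "CYS", "GLY", "PHE", "ILE", "MET", "LEU", "PRO", "TRP", "VAL", "TYR"}

RESIDUE_CLASS: dict[str, str] = (
    {r: "polar" for r in _POLAR}
    | {r: "charged" for r in _CHARGED}
    | {r: "apolar" for r in _APOLAR}
)

# canonical order: charged < polar < apolar, so polar-charged folds into CP,
# apolar-polar into PA, etc.
_CLASS_RANK = {"charged": 0, "polar": 1, "apolar": 2}
_CLASS_LETTER = {"charged": "C", "polar": "P", "apolar": "A"}
CLASS_PAIRS = ("CC", "CP", "CA", "PP", "PA", "AA")

_CUTOFF_RANGE = (3.5, 12.5)


def classify_residue(resname: str) -> str:
    """Return ``charged``, ``polar`` or ``apolar`` for a standard residue."""
    try:
        return RESIDUE_CLASS[resname]
    except KeyError:
        raise KeyError(f"no residue class for non-standard code {resname!r}") from None


def _class_pair(class1: str, class2: str) -> str:
    a, b = sorted((class1, class2), key=_CLASS_RANK.__getitem__)
    return _CLASS_LETTER[a] + _CLASS_LETTER[b]


@dataclass(frozen=True)
class Contact:
    """One residue contact across the interface; ``min_dist`` in angstroms."""

    res1: Residue
    res2: Residue
    min_dist: float


@dataclass
class ContactProfile:
    """Aggregated contact statistics for one interface."""

    rcs: int
    class_counts: dict[str, int]
    aa_counts: dict[str, int]
    res1_count: int
    res2_count: int
    link_density: float
    n_homotypic: int = 0
    cutoff: float = 5.0
    entry_id: str = ""


def compute_contacts(pair: InterfacePair, cutoff: float = 5.0) -> list[Contact]:
    """All residue contacts between the two partners at the given cutoff.

    Uses a k-d tree over the heavy atoms of each side; a residue pair is a
    contact when its minimum inter-atomic distance is strictly below
    ``cutoff``.  Counts are identical to an exhaustive all-atom-pair scan.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if not _CUTOFF_RANGE[0] <= cutoff <= _CUTOFF_RANGE[1]:
        import warnings

        warnings.warn(
            f"cutoff {cutoff} A outside the validated range {_CUTOFF_RANGE}", stacklevel=2
        )

    res1 = pair.partner_structure(1).residues()
    res2 = pair.partner_structure(2).residues()
    if not res1 or not res2:
        return []

    coords1, owner1 = _flatten(res1)
    coords2, owner2 = _flatten(res2)
    tree1, tree2 = cKDTree(coords1), cKDTree(coords2)
    sparse = tree1.sparse_distance_matrix(tree2, max_distance=cutoff, output_type="coo_matrix")

    best: dict[tuple[int, int], float] = {}
    for i, j, dist in zip(sparse.row, sparse.col, sparse.data):
        if dist >= cutoff:  # sparse_distance_matrix is inclusive; RC demands strict <
            continue
        key = (owner1[i], owner2[j])
        if dist < best.get(key, np.inf):
            best[key] = dist
    return [
        Contact(res1=res1[i], res2=res2[j], min_dist=float(d))
        for (i, j), d in sorted(best.items())
    ]


def _flatten(residues: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
    coords = np.concatenate([r.coord_array() for r in residues])
    owner = np.concatenate(
        [np.full(len(r.atoms), idx, dtype=int) for idx, r in enumerate(residues)]
    )
    return coords, owner


def summarize_contacts(
    contacts: list[Contact],
    cutoff: float = 5.0,
    entry_id: str = "",
    count_homotypic_twice: bool = False,
) -> ContactProfile:
    """Fold a contact list into a :class:`ContactProfile`.

    Per-amino-acid counts follow the one-increment convention: a LEU-LEU
    contact is a single RC involving LEU and adds 1 to the LEU count.  Set
    ``count_homotypic_twice`` to add 2 instead (both participants counted).
    """
    class_counts = dict.fromkeys(CLASS_PAIRS, 0)
    aa_counts: dict[str, int] = {}
    side1: set[tuple[str, str]] = set()
    side2: set[tuple[str, str]] = set()
    n_homotypic = 0
    for contact in contacts:
        r1, r2 = contact.res1, contact.res2
        class_counts[_class_pair(classify_residue(r1.resname), classify_residue(r2.resname))] += 1
        if r1.resname == r2.resname:
            n_homotypic += 1
            step = 2 if count_homotypic_twice else 1
            aa_counts[r1.resname] = aa_counts.get(r1.resname, 0) + step
        else:
            aa_counts[r1.resname] = aa_counts.get(r1.resname, 0) + 1
            aa_counts[r2.resname] = aa_counts.get(r2.resname, 0) + 1
        side1.add(r1.key)
        side2.add(r2.key)

    rcs = len(contacts)
    link_density = rcs / (len(side1) * len(side2)) if rcs else 0.0
    return ContactProfile(
        rcs=rcs,
        class_counts=class_counts,
        aa_counts=aa_counts,
        res1_count=len(side1),
        res2_count=len(side2),
        link_density=link_density,
        n_homotypic=n_homotypic,
        cutoff=cutoff,
        entry_id=entry_id,
    )


def contact_table(contacts: list[Contact]):
    """Contacts as a tidy DataFrame (chain/resnum/resname per side, min_dist)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chain1": c.res1.chain_id,
                "resnum1": c.res1.seq_id,
                "resname1": c.res1.resname,
                "chain2": c.res2.chain_id,
                "resnum2": c.res2.seq_id,
                "resname2": c.res2.resname,
                "min_dist": round(c.min_dist, 3),
            }
            for c in contacts
        ],
        columns=["chain1", "resnum1", "resname1", "chain2", "resnum2", "resname2", "min_dist"],
    )
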
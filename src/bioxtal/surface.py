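"""Solvent-accessible surface area, buried surface, and non-interacting surface.

SASA is computed with the Shrake-Rupley algorithm: each atom is surrounded
by a deterministic quasi-uniform shell of test points on the sphere of
radius (vdW radius + probe); the accessible fraction is the fraction of
points not falling inside any neighbouring expanded sphere.  The point
shell is a golden-spiral (Fibonacci) lattice, so identical inputs give
bit-identical output -- there is no random number generator anywhere in
this module.

BSA is the classic difference
``SASA(partner1) + SASA(partner2) - SASA(complex)`` with a 1.4 A water
probe.  The non-interacting surface (NIS) is the set of solvent-exposed
residues whose relative accessibility changes by at most 5 percentage
points between the unbound (partner alone) and bound (complex) forms; its
composition is reported as percentages of polar/apolar/charged residues
(PNIS/ANIS/CNIS).

Tables shipped with the module
------------------------------
``VDW_RADII`` -- Chothia (1976)-type heavy-atom radii as used by NACCESS:
backbone carbonyl carbon 1.76 A, other carbon 1.87 A, nitrogen 1.65 A,
oxygen 1.40 A, sulfur 1.85 A (table version ``chothia-1976/naccess``).

``MAX_ASA`` -- theoretical maximum accessible surface per residue type in
an extended Gly-X-Gly tripeptide, from Tien et al. 2013 (table version
``tien-2013-theoretical``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .contacts import classify_residue
from .structure import EmptyStructureError, InterfacePair, Residue, Structure

__all__ = [
    "VDW_RADII_VERSION",
    "MAX_ASA_VERSION",
    "VDW_RADII",
    "MAX_ASA",
    "SasaRecord",
    "SurfaceProfile",
    "atom_radius",
    "shrake_rupley",
    "compute_sasa",
    "compute_bsa",
    "compute_nis",
    "sasa_table",
]

VDW_RADII_VERSION = "chothia-1976/naccess"
MAX_ASA_VERSION = "tien-2013-theoretical"

#: element-level van der Waals radii (A); the backbone carbonyl carbon
#: (atom name "C") is special-cased to 1.76 A in :func:`atom_radius`.
VDW_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.80, "SE": 1.90}
_DEFAULT_RADIUS = 1.80
_CARBONYL_C_RADIUS = 1.76

#: theoretical maximum ASA (A^2) of residue X in extended Gly-X-Gly
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

#: relative-accessibility thresholds (fractions): a residue is "surface"
#: when its unbound relative SASA is at least SURFACE_THRESHOLD, and NIS
#: when additionally the bound/unbound change is at most NIS_THRESHOLD.
SURFACE_THRESHOLD = 0.05
NIS_THRESHOLD = 0.05


@dataclass
class SasaRecord:
    """Per-residue SASA in bound (complex) and unbound (partner alone) forms."""

    residue: Residue
    sasa_unbound: float
    sasa_bound: float | None = None
    rel_unbound: float | None = None
    rel_bound: float | None = None
    nis: bool | None = None


@dataclass
class SurfaceProfile:
    """Buried surface area and non-interacting-surface composition."""

    bsa: float
    nis_residues: list[Residue]
    pnis: float
    anis: float
    cnis: float
    records: list[SasaRecord]
    nis_defined: bool = True
    entry_id: str = ""


def atom_radius(atom) -> float:
    """Chothia-type radius for a heavy atom (element plus carbonyl special case)."""
    if atom.element == "C" and atom.name == "C":
        return _CARBONYL_C_RADIUS
    return VDW_RADII.get(atom.element.upper(), _DEFAULT_RADIUS)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom SASA (A^2) for arbitrary spheres.

    Exact for an isolated atom up to the point-shell discretization
    (relative error ~ O(1/n_points)).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("coords must be a non-empty (n, 3) array")
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 100:
        raise ValueError("n_points must be at least 100 for a usable estimate")

    unit = _fibonacci_sphere(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(len(coords))
    for idx in range(len(coords)):
        shell = coords[idx] + expanded[idx] * unit
        neighbors = [j for j in tree.query_ball_point(coords[idx], max_reach) if j != idx]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", shell - coords[j], shell - coords[j])
            accessible &= d2 >= expanded[j] ** 2
        areas[idx] = 4.0 * math.pi * expanded[idx] ** 2 * accessible.mean()
    return areas


def compute_sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> list[SasaRecord]:
    """Per-residue absolute SASA of a structure in isolation."""
    residues = structure.residues()
    if not residues:
        raise EmptyStructureError("cannot compute SASA of a structure with no atoms")
    per_residue = _residue_sasa(residues, probe, n_points)
    return [SasaRecord(residue=res, sasa_unbound=value) for res, value in zip(residues, per_residue)]


def _residue_sasa(residues: list[Residue], probe: float, n_points: int) -> np.ndarray:
    coords = np.concatenate([r.coord_array() for r in residues])
    radii = np.array([atom_radius(a) for r in residues for a in r.atoms])
    atom_areas = shrake_rupley(coords, radii, probe=probe, n_points=n_points)
    out = np.empty(len(residues))
    start = 0
    for i, res in enumerate(residues):
        stop = start + len(res.atoms)
        out[i] = atom_areas[start:stop].sum()
        start = stop
    return out


def compute_bsa(
    pair: InterfacePair,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """Buried surface area: SASA(p1) + SASA(p2) - SASA(complex), clipped at 0."""
    total = 0.0
    for which in (1, 2):
        partner = pair.partner_structure(which).residues()
        total += _residue_sasa(partner, probe, n_points).sum()
    complex_residues = pair.structure.subset(pair.partner1 | pair.partner2).residues()
    total -= _residue_sasa(complex_residues, probe, n_points).sum()
    if total < 0:
        if total < -0.5:
            warnings.warn(f"negative BSA {total:.3f} A^2 clipped to 0", stacklevel=2)
        total = 0.0
    return float(total)


def compute_nis(
    pair: InterfacePair,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    surface_threshold: float = SURFACE_THRESHOLD,
    nis_threshold: float = NIS_THRESHOLD,
    entry_id: str = "",
) -> SurfaceProfile:
    """BSA plus the non-interacting-surface composition of an interface.

    Both SASA runs (partners alone, complex) are done per residue, so the
    returned BSA equals the sum of per-residue burials exactly.
    """
    records: list[SasaRecord] = []
    complex_structure = pair.structure.subset(pair.partner1 | pair.partner2)
    complex_residues = complex_structure.residues()
    bound = _residue_sasa(complex_residues, probe, n_points)
    bound_by_key = {res.key: s for res, s in zip(complex_residues, bound)}

    bsa = 0.0
    for which in (1, 2):
        partner = pair.partner_structure(which).residues()
        unbound = _residue_sasa(partner, probe, n_points)
        for res, sasa_u in zip(partner, unbound):
            sasa_b = bound_by_key[res.key]
            max_asa = MAX_ASA[res.resname]
            rel_u, rel_b = sasa_u / max_asa, sasa_b / max_asa
            is_nis = rel_u >= surface_threshold and abs(rel_u - rel_b) <= nis_threshold
            records.append(
                SasaRecord(
                    residue=res,
                    sasa_unbound=float(sasa_u),
                    sasa_bound=float(sasa_b),
                    rel_unbound=float(rel_u),
                    rel_bound=float(rel_b),
                    nis=is_nis,
                )
            )
            bsa += sasa_u - sasa_b
    if bsa < 0:
        if bsa < -0.5:
            warnings.warn(f"negative BSA {bsa:.3f} A^2 clipped to 0", stacklevel=2)
        bsa = 0.0

    nis_residues = [rec.residue for rec in records if rec.nis]
    if nis_residues:
        counts = {"polar": 0, "apolar": 0, "charged": 0}
        for res in nis_residues:
            counts[classify_residue(res.resname)] += 1
        n = len(nis_residues)
        pnis, anis, cnis = (100.0 * counts[k] / n for k in ("polar", "apolar", "charged"))
        defined = True
    else:
        warnings.warn("empty NIS set; composition percentages are undefined", stacklevel=2)
        pnis = anis = cnis = float("nan")
        defined = False
    return SurfaceProfile(
        bsa=float(bsa),
        nis_residues=nis_residues,
        pnis=pnis,
        anis=anis,
        cnis=cnis,
        records=records,
        nis_defined=defined,
        entry_id=entry_id,
    )


def sasa_table(profile: SurfaceProfile):
    """Per-residue SASA records as a tidy DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chain": rec.residue.chain_id,
                "resnum": rec.residue.seq_id,
                "resname": rec.residue.resname,
                "sasa_bound": rec.sasa_bound,
                "sasa_unbound": rec.sasa_unbound,
                "rel_bound": rec.rel_bound,
                "rel_unbound": rec.rel_unbound,
                "nis_flag": rec.nis,
            }
            for rec in profile.records
        ]
    )
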
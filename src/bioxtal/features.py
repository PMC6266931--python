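"""Named feature sets for interface classification, and their tabular I/O.

Feature sets
------------
========  ===========================================================  ======
name      contents                                                     length
========  ===========================================================  ======
S1        BSA                                                          1
S2        RCs (total residue contacts)                                 1
S3        six class-pair counts CC, CP, CA, PP, AP, AA                 6
S4        S3 + ANIS, CNIS, PNIS                                        9
S5        S3 + LD + 20 per-amino-acid contact counts                   27
S6        S3 + ANIS, CNIS, PNIS + LD + 20 amino acids                  30
E1        HS (composite external score)                                1
E2        Eelec, Evdw, Edes                                            3
C         S6 + E2                                                      33
FINAL22   S5 minus {K, CC, W, N, PP} (pruned by feature selection)     22
========  ===========================================================  ======

``AP`` is the polar-apolar class-pair count (the same bin as ``PA``); the
amino-acid columns use one-letter codes.  Energetic columns are external
inputs (computed upstream by a refinement engine), never calculated here.

Tables are TSV/CSV with an ``entry_id`` column, one column per feature and
an optional ``class`` column with labels ``bio``/``xtal`` (bio is the
positive class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactProfile
from .surface import SurfaceProfile

__all__ = [
    "AA_ORDER",
    "FEATURE_SETS",
    "LABELS",
    "EnergyRecord",
    "FeatureVector",
    "assemble_features",
    "read_energy_table",
    "write_feature_table",
    "read_feature_table",
]

_ONE_LETTER = {
    "GLY": "G", "ALA": "A", "LEU": "L", "MET": "M", "PHE": "F", "TRP": "W",
    "LYS": "K", "GLN": "Q", "GLU": "E", "SER": "S", "PRO": "P", "VAL": "V",
    "ILE": "I", "CYS": "C", "TYR": "Y", "HIS": "H", "ARG": "R", "ASN": "N",
    "ASP": "D", "THR": "T",
}

#: per-amino-acid feature order (one-letter codes)
AA_ORDER = ("G", "A", "L", "M", "F", "W", "K", "Q", "E", "S",
            "P", "V", "I", "C", "Y", "H", "R", "N", "D", "T")

_S3 = ("CC", "CP", "CA", "PP", "AP", "AA")
_NIS = ("ANIS", "CNIS", "PNIS")
_E2 = ("Eelec", "Evdw", "Edes")
_S5 = _S3 + ("LD",) + AA_ORDER
_PRUNED = {"K", "CC", "W", "N", "PP"}

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "S1": ("BSA",),
    "S2": ("RCs",),
    "S3": _S3,
    "S4": _S3 + _NIS,
    "S5": _S5,
    "S6": _S3 + _NIS + ("LD",) + AA_ORDER,
    "E1": ("HS",),
    "E2": _E2,
    "C": _S3 + _NIS + ("LD",) + AA_ORDER + _E2,
    "FINAL22": tuple(name for name in _S5 if name not in _PRUNED),
}

_ENERGY_SETS = {"E1", "E2", "C"}

LABELS = ("bio", "xtal")  # bio is the positive class


@dataclass
class EnergyRecord:
    """Externally computed interaction energetics for one entry."""

    entry_id: str
    eelec: float
    evdw: float
    edes: float
    hs: float = float("nan")


@dataclass
class FeatureVector:
    """Ordered numeric features for one entry under a named feature set."""

    feature_set: str
    names: tuple[str, ...]
    values: np.ndarray
    entry_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values must have equal length")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


class MissingEnergeticsError(ValueError):
    """An energetic feature set was requested without an energy record."""


def assemble_features(
    contact_profile: ContactProfile,
    surface_profile: SurfaceProfile | None = None,
    energy: EnergyRecord | None = None,
    feature_set: str = "FINAL22",
    entry_id: str | None = None,
) -> FeatureVector:
    """Build the ordered feature vector of a named set from computed profiles."""
    try:
        names = FEATURE_SETS[feature_set]
    except KeyError:
        raise KeyError(
            f"unknown feature set {feature_set!r}; choose from {sorted(FEATURE_SETS)}"
        ) from None
    if feature_set in _ENERGY_SETS and energy is None:
        raise MissingEnergeticsError(
            f"feature set {feature_set} needs an external energy record (Eelec/Evdw/Edes/HS)"
        )

    source: dict[str, float] = {}
    if contact_profile is not None:
        counts = contact_profile.class_counts
        source.update(
            RCs=contact_profile.rcs,
            LD=contact_profile.link_density,
            CC=counts.get("CC", 0), CP=counts.get("CP", 0), CA=counts.get("CA", 0),
            PP=counts.get("PP", 0), AP=counts.get("PA", 0), AA=counts.get("AA", 0),
        )
        for three, one in _ONE_LETTER.items():
            source[one] = contact_profile.aa_counts.get(three, 0)
    if surface_profile is not None:
        source.update(
            BSA=surface_profile.bsa,
            ANIS=surface_profile.anis,
            CNIS=surface_profile.cnis,
            PNIS=surface_profile.pnis,
        )
    if energy is not None:
        source.update(Eelec=energy.eelec, Evdw=energy.evdw, Edes=energy.edes, HS=energy.hs)

    missing = [n for n in names if n not in source]
    if missing:
        raise ValueError(f"cannot assemble {feature_set}: missing inputs for {missing}")
    if entry_id is None:
        entry_id = contact_profile.entry_id if contact_profile is not None else ""
    return FeatureVector(
        feature_set=feature_set,
        names=names,
        values=np.array([source[n] for n in names], dtype=float),
        entry_id=entry_id,
    )


def read_energy_table(path) -> dict[str, EnergyRecord]:
    """Read a TSV of external energetics keyed by entry_id."""
    table = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"entry_id", "eelec", "evdw", "edes"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"energy table is missing columns {sorted(missing)}")
    records = {}
    for row in table.itertuples(index=False):
        records[str(row.entry_id)] = EnergyRecord(
            entry_id=str(row.entry_id),
            eelec=float(row.eelec),
            evdw=float(row.evdw),
            edes=float(row.edes),
            hs=float(getattr(row, "hs", float("nan"))),
        )
    return records


def write_feature_table(vectors: list[FeatureVector], path, labels=None) -> None:
    """Write feature vectors (one set) to TSV, optionally with a class column."""
    if not vectors:
        raise ValueError("no feature vectors to write")
    sets = {v.feature_set for v in vectors}
    if len(sets) != 1:
        raise ValueError(f"mixed feature sets in one table: {sorted(sets)}")
    frame = vectors_to_frame(vectors)
    if labels is not None:
        if len(labels) != len(vectors):
            raise ValueError("labels and vectors length mismatch")
        bad = set(labels) - set(LABELS)
        if bad:
            raise ValueError(f"labels must be in {LABELS}, got {sorted(bad)}")
        frame["class"] = list(labels)
    frame.to_csv(path, sep="\t", index=False)


def vectors_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    names = vectors[0].names
    frame = pd.DataFrame(np.vstack([v.values for v in vectors]), columns=list(names))
    frame.insert(0, "entry_id", [v.entry_id for v in vectors])
    return frame


def read_feature_table(path, feature_set: str | None = None):
    """Read a feature table; returns ``(vectors, labels_or_None)``.

    The feature set is inferred from the header when not given; any column
    that is neither ``entry_id``, ``class`` nor a feature of the set is an
    error.
    """
    frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    feature_cols = [c for c in frame.columns if c not in ("entry_id", "class")]
    if feature_set is None:
        feature_set = _infer_feature_set(feature_cols)
    names = FEATURE_SETS[feature_set]
    unknown = [c for c in feature_cols if c not in names]
    if unknown:
        raise ValueError(f"unknown column(s) for feature set {feature_set}: {unknown}")
    missing = [n for n in names if n not in feature_cols]
    if missing:
        raise ValueError(f"feature table is missing column(s) {missing}")

    entry_ids = (
        frame["entry_id"].astype(str).tolist()
        if "entry_id" in frame.columns
        else [str(i) for i in range(len(frame))]
    )
    vectors = [
        FeatureVector(
            feature_set=feature_set,
            names=names,
            values=frame.loc[idx, list(names)].to_numpy(dtype=float),
            entry_id=entry_ids[i],
        )
        for i, idx in enumerate(frame.index)
    ]
    labels = None
    if "class" in frame.columns:
        bad = set(frame["class"]) - set(LABELS)
        if bad:
            raise ValueError(f"unknown class label(s) {sorted(bad)}; expected {LABELS}")
        labels = frame["class"].tolist()
    return vectors, labels


def _infer_feature_set(feature_cols: list[str]) -> str:
    cols = set(feature_cols)
    # prefer the most specific match (exact column set), longest first
    for name, names in sorted(FEATURE_SETS.items(), key=lambda kv: -len(kv[1])):
        if cols == set(names):
            return name
    raise ValueError(f"columns {sorted(cols)} match no known feature set")
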
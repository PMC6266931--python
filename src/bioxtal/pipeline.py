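"""End-to-end featurization: coordinate file -> named feature vector.

:class:`InterfaceFeaturizer` is a stateless scikit-learn transformer that
maps PDB paths (or ready :class:`~bioxtal.structure.InterfacePair` objects)
to a feature DataFrame, so it composes directly with sklearn pipelines and
the :class:`~bioxtal.classifier.InterfaceClassifier` estimator.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .contacts import compute_contacts, summarize_contacts
from .features import (
    FEATURE_SETS,
    EnergyRecord,
    FeatureVector,
    assemble_features,
    read_energy_table,
)
from .structure import InterfacePair, load_structure, make_interface_pair
from .surface import DEFAULT_N_POINTS, DEFAULT_PROBE, compute_nis

__all__ = ["InterfaceFeaturizer", "featurize_pair", "featurize_file"]

_SURFACE_FEATURES = {"BSA", "ANIS", "CNIS", "PNIS"}


def _needs_surface(feature_set: str) -> bool:
    return bool(_SURFACE_FEATURES & set(FEATURE_SETS[feature_set]))


def featurize_pair(
    pair: InterfacePair,
    feature_set: str = "FINAL22",
    cutoff: float = 5.0,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    energy: EnergyRecord | None = None,
    entry_id: str = "",
    count_homotypic_twice: bool = False,
) -> FeatureVector:
    """Contacts (and surface, when the set needs it) -> feature vector."""
    contacts = compute_contacts(pair, cutoff=cutoff)
    profile = summarize_contacts(
        contacts, cutoff=cutoff, entry_id=entry_id, count_homotypic_twice=count_homotypic_twice
    )
    surface = (
        compute_nis(pair, probe=probe, n_points=n_points, entry_id=entry_id)
        if _needs_surface(feature_set)
        else None
    )
    return assemble_features(
        profile, surface, energy=energy, feature_set=feature_set, entry_id=entry_id
    )


def featurize_file(
    path,
    feature_set: str = "FINAL22",
    partner1=(),
    partner2=(),
    cutoff: float = 5.0,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    energy: EnergyRecord | None = None,
    count_homotypic_twice: bool = False,
) -> FeatureVector:
    """Load, sanitize, partition and featurize one coordinate file."""
    structure = load_structure(path)
    pair = make_interface_pair(structure, partner1, partner2)
    return featurize_pair(
        pair,
        feature_set=feature_set,
        cutoff=cutoff,
        probe=probe,
        n_points=n_points,
        energy=energy,
        entry_id=Path(path).stem,
        count_homotypic_twice=count_homotypic_twice,
    )


class InterfaceFeaturizer(TransformerMixin, BaseEstimator):
    """Transform coordinate files or interface pairs into feature rows.

    Parameters
    ----------
    feature_set : named set (``S1``..``S6``, ``E1``, ``E2``, ``C`` or
        ``FINAL22``; default ``FINAL22``, the production manifest).
    cutoff : residue-contact distance cutoff in angstroms (default 5.0).
    probe : water-probe radius for SASA (default 1.4 A).
    n_points : Shrake-Rupley sphere points per atom (default 960).
    partner1, partner2 : chain groupings applied to every input file; empty
        means the two-chain default split.
    energies : path to an external energetics TSV (entry_id, eelec, evdw,
        edes[, hs]); required for the E1/E2/C sets.

    The transformer is stateless: ``fit`` records nothing and ``transform``
    is deterministic.
    """

    def __init__(
        self,
        feature_set: str = "FINAL22",
        cutoff: float = 5.0,
        probe: float = DEFAULT_PROBE,
        n_points: int = DEFAULT_N_POINTS,
        partner1=(),
        partner2=(),
        energies=None,
        count_homotypic_twice: bool = False,
    ):
        self.feature_set = feature_set
        self.cutoff = cutoff
        self.probe = probe
        self.n_points = n_points
        self.partner1 = partner1
        self.partner2 = partner2
        self.energies = energies
        self.count_homotypic_twice = count_homotypic_twice

    def fit(self, X=None, y=None):
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        return self

    def transform(self, X) -> pd.DataFrame:
        """X: iterable of PDB paths or InterfacePair objects -> DataFrame."""
        self.fit()
        energy_records = (
            read_energy_table(self.energies) if self.energies is not None else {}
        )
        vectors = [self._one(item, energy_records) for item in X]
        frame = pd.DataFrame(
            [v.as_dict() for v in vectors], columns=list(FEATURE_SETS[self.feature_set])
        )
        frame.index = pd.Index([v.entry_id for v in vectors], name="entry_id")
        return frame

    def transform_vectors(self, X) -> list[FeatureVector]:
        self.fit()
        energy_records = (
            read_energy_table(self.energies) if self.energies is not None else {}
        )
        return [self._one(item, energy_records) for item in X]

    def _one(self, item, energy_records) -> FeatureVector:
        if isinstance(item, InterfacePair):
            entry_id = item.structure.source_id or "pair"
            return featurize_pair(
                item,
                feature_set=self.feature_set,
                cutoff=self.cutoff,
                probe=self.probe,
                n_points=self.n_points,
                energy=energy_records.get(entry_id),
                entry_id=entry_id,
                count_homotypic_twice=self.count_homotypic_twice,
            )
        entry_id = Path(item).stem
        return featurize_file(
            item,
            feature_set=self.feature_set,
            partner1=self.partner1,
            partner2=self.partner2,
            cutoff=self.cutoff,
            probe=self.probe,
            n_points=self.n_points,
            energy=energy_records.get(entry_id),
            count_homotypic_twice=self.count_homotypic_twice,
        )
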
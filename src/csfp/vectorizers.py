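"""Scikit-learn-style fingerprint transformers.

``CSFPVectorizer.fit`` derives the fragment library from the training
compounds (analogue-series cores → ring fragments; cuts → substituents) and
``transform`` produces the binary fingerprint matrix. ``MACCSVectorizer`` and
``ECFPVectorizer`` wrap the RDKit comparators with the same interface so the
three fingerprints are interchangeable in pipelines and benchmarks.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .chem_io import MoleculeRecord, standardize
from .fingerprint import FragmentLibrary, build_library_from_molecules, compute_matrix

__all__ = ["CSFPVectorizer", "MACCSVectorizer", "ECFPVectorizer"]


def _records(X: Iterable) -> list[MoleculeRecord]:
    out = []
    for i, item in enumerate(X):
        if isinstance(item, MoleculeRecord):
            out.append(item)
        elif isinstance(item, Chem.Mol):
            out.append(
                MoleculeRecord(id=f"mol{i}", smiles=Chem.MolToSmiles(item), mol=item)
            )
        else:
            out.append(standardize(str(item), mol_id=f"mol{i}"))
    return out


class CSFPVectorizer(BaseEstimator, TransformerMixin):
    """Core-substituent fingerprint transformer.

    Parameters mirror the library pipeline: category quotas (``n_single`` /
    ``n_fused`` / ``n_substituents``, default 250/250/500 → 1000 bits), the
    fragmentation settings (``max_cuts`` exocyclic bonds, ``ratio`` minimum
    core:substituent size ratio), and whether the retrosynthetic substituent
    source is used. Pass a prebuilt ``library`` to skip fitting.

    Attributes
    ----------
    library_ : FragmentLibrary
        The fitted fragment catalog with bit-index map and closure graph.
    n_bits_ : int
        Fingerprint length (sum of the selected category sizes).
    """

    def __init__(
        self,
        n_single: int = 250,
        n_fused: int = 250,
        n_substituents: int = 500,
        max_cuts: int = 5,
        ratio: float = 2.0,
        min_members: int = 2,
        use_retrosynthetic: bool = True,
        max_exocyclic_bonds: int = 25,
        library: FragmentLibrary | None = None,
    ):
        self.n_single = n_single
        self.n_fused = n_fused
        self.n_substituents = n_substituents
        self.max_cuts = max_cuts
        self.ratio = ratio
        self.min_members = min_members
        self.use_retrosynthetic = use_retrosynthetic
        self.max_exocyclic_bonds = max_exocyclic_bonds
        self.library = library

    def fit(self, X: Iterable, y=None):
        if self.library is not None:
            self.library_ = self.library
        else:
            self.library_ = build_library_from_molecules(
                _records(X),
                n_single=self.n_single,
                n_fused=self.n_fused,
                n_subs=self.n_substituents,
                max_cuts=self.max_cuts,
                ratio=self.ratio,
                min_members=self.min_members,
                retro_cutter="default" if self.use_retrosynthetic else None,
                max_exocyclic_bonds=self.max_exocyclic_bonds,
            )
        self.n_bits_ = self.library_.n_bits
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        check_is_fitted(self, "library_")
        return compute_matrix(_records(X), self.library_)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "library_")
        return np.array([f.pattern for f in self.library_.fragments], dtype=object)


class MACCSVectorizer(BaseEstimator, TransformerMixin):
    """166-bit MACCS structural keys (RDKit; bit 0 unused and dropped)."""

    def fit(self, X: Iterable = (), y=None):
        self.n_bits_ = 166
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        check_is_fitted(self, "n_bits_")
        rows = []
        for rec in _records(X):
            fp = MACCSkeys.GenMACCSKeys(rec.mol)
            arr = np.zeros(167, dtype=np.uint8)
            for bit in fp.GetOnBits():
                arr[bit] = 1
            rows.append(arr[1:])
        return np.vstack(rows) if rows else np.zeros((0, 166), dtype=np.uint8)


class ECFPVectorizer(BaseEstimator, TransformerMixin):
    """Folded extended-connectivity fingerprint (default ECFP4: radius 2, 1024 bits)."""

    def __init__(self, radius: int = 2, n_bits: int = 1024):
        self.radius = radius
        self.n_bits = n_bits

    def fit(self, X: Iterable = (), y=None):
        self._generator_ = rdFingerprintGenerator.GetMorganGenerator(
            radius=self.radius, fpSize=self.n_bits
        )
        self.n_bits_ = self.n_bits
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        check_is_fitted(self, "n_bits_")
        rows = []
        for rec in _records(X):
            fp = self._generator_.GetFingerprint(rec.mol)
            arr = np.zeros(self.n_bits, dtype=np.uint8)
            for bit in fp.GetOnBits():
                arr[bit] = 1
            rows.append(arr)
        return np.vstack(rows) if rows else np.zeros((0, self.n_bits), dtype=np.uint8)
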
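"""Proteochemometric featurization of mutant-drug pairs.

A pair is encoded as the concatenation of a protein block and a drug block:

* protein: the mutant sequence, trimmed to the window covering all mutated
  positions in the dataset, encoded residue-by-residue with five-component
  z-scales (5·L values for a trimmed length L);
* drug: a 2048-bit Morgan/ECFP fingerprint of radius 2.

The z-scale block is standardized to zero mean and unit variance using
statistics of the training partition only; fingerprint bits pass through
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import RDLogger

from .exceptions import AssemblyError, ChemistryError, DimensionError, EncodingError
from .mutants import MutantSpec, TrimRegion, apply_substitutions, compute_trim_region
from .zscales import N_COMPONENTS, ZScaleTable, load_zscale_table

RDLogger.DisableLog("rdApp.error")

FINGERPRINT_BITS = 2048
FINGERPRINT_RADIUS = 2


def zscale_encode(sequence: str, table: ZScaleTable | None = None) -> np.ndarray:
    """Encode a protein sequence as its concatenated z-scale scores.

    Residue ``i`` of the sequence occupies slots ``[5i, 5i+5)`` of the output.
    """
    table = table if table is not None else load_zscale_table()
    out = np.empty(N_COMPONENTS * len(sequence), dtype=float)
    for i, aa in enumerate(sequence):
        try:
            out[N_COMPONENTS * i : N_COMPONENTS * (i + 1)] = table[aa]
        except KeyError:
            raise EncodingError(f"residue {aa!r} at position {i + 1} has no z-scale entry") from None
    return out


def fingerprint_encode(
    smiles: str,
    radius: int = FINGERPRINT_RADIUS,
    n_bits: int = FINGERPRINT_BITS,
) -> np.ndarray:
    """Binary Morgan (ECFP) fingerprint of a molecule given as SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprintAsNumPy(mol).astype(float)


@dataclass(frozen=True)
class FeatureVector:
    """Concatenated per-pair features: z-scale block first, then fingerprint."""

    zscale_block: np.ndarray
    fingerprint_block: np.ndarray

    def __post_init__(self) -> None:
        if self.fingerprint_block.shape != (FINGERPRINT_BITS,):
            raise AssemblyError(
                f"fingerprint block must have {FINGERPRINT_BITS} bits, got "
                f"{self.fingerprint_block.shape}"
            )
        if self.zscale_block.ndim != 1 or self.zscale_block.size % N_COMPONENTS != 0:
            raise AssemblyError(
                f"z-scale block length {self.zscale_block.size} is not a "
                f"multiple of {N_COMPONENTS}"
            )
        fp = np.asarray(self.fingerprint_block)
        if not np.isin(fp, (0.0, 1.0)).all():
            raise AssemblyError("fingerprint block must be binary")

    @property
    def boundary(self) -> int:
        """Index of the first fingerprint column in the combined vector."""
        return int(self.zscale_block.size)

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.zscale_block, self.fingerprint_block])

    def __len__(self) -> int:
        return self.zscale_block.size + self.fingerprint_block.size


def assemble_features(zvec: np.ndarray, fp: np.ndarray) -> FeatureVector:
    """Pair a protein z-scale vector with a drug fingerprint."""
    return FeatureVector(np.asarray(zvec, dtype=float), np.asarray(fp, dtype=float))


class Standardizer:
    """Column standardizer for the z-scale block of a feature matrix.

    Fit on the training partition only; columns left of ``boundary`` are
    shifted/scaled to zero mean and unit variance, zero-variance columns map
    to 0, and fingerprint columns pass through untouched.
    """

    def __init__(self, boundary: int):
        self.boundary = int(boundary)
        self.means_: np.ndarray | None = None
        self.stds_: np.ndarray | None = None
        self.n_features_: int | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < self.boundary:
            raise DimensionError(
                f"cannot fit standardizer with boundary {self.boundary} on "
                f"matrix of shape {X.shape}"
            )
        block = X[:, : self.boundary]
        self.means_ = block.mean(axis=0)
        self.stds_ = block.std(axis=0)
        self.n_features_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.means_ is None:
            raise DimensionError("standardizer is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise DimensionError(
                f"expected {self.n_features_} feature columns, got {X.shape}"
            )
        out = X.copy()
        block = out[:, : self.boundary]
        nonzero = self.stds_ > 0
        block[:, nonzero] = (block[:, nonzero] - self.means_[nonzero]) / self.stds_[nonzero]
        block[:, ~nonzero] = 0.0
        out[:, : self.boundary] = block
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        return {
            "boundary": self.boundary,
            "means": None if self.means_ is None else self.means_.tolist(),
            "stds": None if self.stds_ is None else self.stds_.tolist(),
            "n_features": self.n_features_,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Standardizer":
        s = cls(d["boundary"])
        if d.get("means") is not None:
            s.means_ = np.asarray(d["means"], dtype=float)
            s.stds_ = np.asarray(d["stds"], dtype=float)
            s.n_features_ = int(d["n_features"])
        return s


def fit_standardizer(train_features: np.ndarray, boundary: int) -> Standardizer:
    return Standardizer(boundary).fit(train_features)


def apply_standardizer(params: Standardizer, features: np.ndarray) -> np.ndarray:
    return params.transform(features)


def featurize_pairs(
    wt_sequence: str,
    specs: Sequence[MutantSpec],
    smiles_by_drug: Mapping[str, str],
    pairs: Sequence[tuple[str, str]],
    region: TrimRegion | None = None,
    table: ZScaleTable | None = None,
) -> tuple[np.ndarray, int, TrimRegion]:
    """Build the raw (unstandardized) feature matrix for mutant-drug pairs.

    Returns the matrix (one row per pair, ordered as ``pairs``), the z-scale /
    fingerprint block boundary, and the trim region used.  When ``region`` is
    None it is computed from the specs (zero padding), which is the default
    protocol: one shared window so all vectors have equal length.
    """
    spec_by_id = {s.mutant_id: s for s in specs}
    if region is None:
        region = compute_trim_region(specs)
    zcache: dict[str, np.ndarray] = {}
    for spec in specs:
        mutated = apply_substitutions(wt_sequence, spec)
        zcache[spec.mutant_id] = zscale_encode(region.extract(mutated), table)
    fpcache = {d: fingerprint_encode(smi) for d, smi in smiles_by_drug.items()}
    rows = []
    for mutant_id, drug_id in pairs:
        if mutant_id not in zcache:
            raise KeyError(f"pair references unknown mutant {mutant_id!r}")
        if drug_id not in fpcache:
            raise KeyError(f"pair references unknown drug {drug_id!r}")
        rows.append(assemble_features(zcache[mutant_id], fpcache[drug_id]).combined)
    X = np.vstack(rows) if rows else np.empty((0, 0))
    boundary = next(iter(zcache.values())).size if zcache else 0
    return X, boundary, region
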
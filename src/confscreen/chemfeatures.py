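"""Featurization: physicochemical descriptors and modulo-folded fingerprints.

Two feature spaces are supported, matching common practice in HTS machine
learning: a fixed block of 97 physicochemical/structural RDKit descriptors,
and full-length (unfolded) Morgan circular fingerprints whose raw hash
indices are folded onto a fixed-width binary vector by taking each index
modulo the vector length. Folding is binary: pre-fold multiplicities are
discarded, a bit is set as soon as any raw index lands on it.

Structure standardization (tautomers, salts, charges) is intentionally out
of scope; ``standardize_hook`` lets callers plug in their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._exceptions import InputError, ParameterError

__all__ = [
    "DEFAULT_DESCRIPTORS",
    "DescriptorConfig",
    "hash_fingerprint_indices",
    "morgan_raw_indices",
    "compute_fingerprints",
    "compute_descriptors",
    "read_smiles_table",
]

# Default descriptor block: 97 RDKit descriptor names covering bulk
# properties, topological indices, atom/ring counts and the three
# surface-area partition families (SlogP/SMR/PEOE) plus EState summaries.
# The width matches descriptor sets used in published HTS models; the
# exact membership is a package choice and fully overridable.
DEFAULT_DESCRIPTORS: tuple[str, ...] = (
    # bulk / constitutional
    "MolWt", "HeavyAtomMolWt", "ExactMolWt", "NumValenceElectrons",
    "NumRadicalElectrons", "qed", "FractionCSP3", "TPSA", "MolLogP",
    "MolMR", "LabuteASA",
    # topological indices
    "BalabanJ", "BertzCT", "HallKierAlpha", "Kappa1", "Kappa2", "Kappa3",
    "Chi0", "Chi0n", "Chi0v", "Chi1", "Chi1n", "Chi1v",
    "Chi2n", "Chi2v", "Chi3n", "Chi3v", "Chi4n", "Chi4v",
    # counts
    "HeavyAtomCount", "NHOHCount", "NOCount", "NumHAcceptors", "NumHDonors",
    "NumHeteroatoms", "NumRotatableBonds", "RingCount",
    "NumAromaticRings", "NumAliphaticRings", "NumSaturatedRings",
    "NumAromaticCarbocycles", "NumAromaticHeterocycles",
    "NumAliphaticCarbocycles", "NumAliphaticHeterocycles",
    "NumSaturatedCarbocycles", "NumSaturatedHeterocycles",
    # SlogP_VSA surface-area bins
    "SlogP_VSA1", "SlogP_VSA2", "SlogP_VSA3", "SlogP_VSA4", "SlogP_VSA5",
    "SlogP_VSA6", "SlogP_VSA7", "SlogP_VSA8", "SlogP_VSA9", "SlogP_VSA10",
    "SlogP_VSA11", "SlogP_VSA12",
    # SMR_VSA bins
    "SMR_VSA1", "SMR_VSA2", "SMR_VSA3", "SMR_VSA4", "SMR_VSA5",
    "SMR_VSA6", "SMR_VSA7", "SMR_VSA8", "SMR_VSA9", "SMR_VSA10",
    # PEOE_VSA bins (Gasteiger-charge partitioned)
    "PEOE_VSA1", "PEOE_VSA2", "PEOE_VSA3", "PEOE_VSA4", "PEOE_VSA5",
    "PEOE_VSA6", "PEOE_VSA7", "PEOE_VSA8", "PEOE_VSA9", "PEOE_VSA10",
    "PEOE_VSA11", "PEOE_VSA12", "PEOE_VSA13", "PEOE_VSA14",
    # EState summaries and bins
    "EState_VSA1", "EState_VSA2", "EState_VSA3", "EState_VSA4",
    "EState_VSA5", "EState_VSA6", "EState_VSA7", "EState_VSA8",
    "EState_VSA9", "EState_VSA10", "EState_VSA11",
    "MaxEStateIndex", "MinEStateIndex", "MaxAbsEStateIndex",
    "MinAbsEStateIndex",
)
assert len(DEFAULT_DESCRIPTORS) == 97


@dataclass(frozen=True)
class DescriptorConfig:
    """Featurization settings: descriptor list and fingerprint geometry."""

    descriptor_names: tuple[str, ...] = DEFAULT_DESCRIPTORS
    fingerprint_bits: int = 4096
    fingerprint_radius: int = 2

    def __post_init__(self) -> None:
        if not self.descriptor_names:
            raise ParameterError("descriptor_names must be nonempty")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ParameterError("descriptor_names must be duplicate-free")
        if self.fingerprint_bits < 1:
            raise ParameterError("fingerprint_bits must be >= 1")
        if self.fingerprint_radius < 0:
            raise ParameterError("fingerprint_radius must be >= 0")


def hash_fingerprint_indices(
    raw_indices: Sequence[int], n_bits: int
) -> np.ndarray:
    """Fold raw fingerprint hash indices onto an ``n_bits`` binary vector.

    Bit ``j`` is set iff some raw index ``i`` satisfies ``i % n_bits == j``;
    order and multiplicity of the input indices are irrelevant.
    """
    if n_bits < 1:
        raise ParameterError("n_bits must be >= 1")
    idx = np.asarray(list(raw_indices), dtype=np.int64)
    vector = np.zeros(n_bits, dtype=np.int8)
    if idx.size == 0:
        return vector
    if (idx < 0).any():
        raise InputError("fingerprint indices must be nonnegative")
    vector[np.unique(idx % n_bits)] = 1
    return vector


def _parse_mols(smiles, standardize_hook):
    from rdkit import Chem

    mols, failures = [], {}
    for pos, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi) if isinstance(smi, str) else None
        if mol is not None and standardize_hook is not None:
            mol = standardize_hook(mol)
        if mol is None:
            failures[pos] = f"unparsable SMILES: {smi!r}"
        else:
            mols.append((pos, mol))
    return mols, failures


def morgan_raw_indices(mol, radius: int = 2) -> list[int]:
    """Raw (unfolded) Morgan fingerprint hash indices of one molecule."""
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    return sorted(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())


def compute_fingerprints(
    smiles: Sequence[str],
    config: DescriptorConfig | None = None,
    standardize_hook: Callable | None = None,
) -> tuple[np.ndarray, list[int], dict[int, str]]:
    """Folded binary Morgan fingerprints for a SMILES list.

    Returns ``(matrix, kept_positions, failures)``; rows of ``matrix``
    correspond to the input positions in ``kept_positions`` and failures
    maps input position to a reason. All inputs failing is an error.
    """
    config = config or DescriptorConfig()
    mols, failures = _parse_mols(smiles, standardize_hook)
    if not mols:
        raise InputError("no SMILES could be parsed")
    rows = [
        hash_fingerprint_indices(
            morgan_raw_indices(mol, config.fingerprint_radius),
            config.fingerprint_bits,
        )
        for _, mol in mols
    ]
    return np.vstack(rows).astype(np.float64), [p for p, _ in mols], failures


def compute_descriptors(
    smiles: Sequence[str],
    config: DescriptorConfig | None = None,
    standardize_hook: Callable | None = None,
) -> tuple[np.ndarray, list[int], dict[int, str]]:
    """Physicochemical descriptor matrix for a SMILES list.

    One row per successfully processed input, columns ordered exactly as
    ``config.descriptor_names``. A compound for which any descriptor fails
    (or returns a non-finite value) is excluded and reported in the
    failures dict — silent imputation would corrupt conformal calibration
    downstream. All inputs failing is an error.
    """
    from rdkit.Chem import Descriptors

    config = config or DescriptorConfig()
    funcs = []
    for name in config.descriptor_names:
        func = getattr(Descriptors, name, None)
        if func is None:
            raise ParameterError(f"unknown RDKit descriptor: {name}")
        funcs.append(func)

    mols, failures = _parse_mols(smiles, standardize_hook)
    rows, kept = [], []
    for pos, mol in mols:
        try:
            row = np.array([f(mol) for f in funcs], dtype=np.float64)
        except Exception as exc:  # descriptor-specific failure
            failures[pos] = f"descriptor error: {exc}"
            continue
        if not np.isfinite(row).all():
            bad = config.descriptor_names[int(np.flatnonzero(~np.isfinite(row))[0])]
            failures[pos] = f"non-finite descriptor: {bad}"
            continue
        rows.append(row)
        kept.append(pos)
    if not rows:
        raise InputError("no compound yielded a complete descriptor row")
    return np.vstack(rows), kept, failures


def read_smiles_table(path: str | Path) -> pd.DataFrame:
    """Read compounds from CSV (compound_id, smiles[, label]) or a plain
    SMILES file (``smiles [id]`` per line, whitespace-separated)."""
    path = Path(path)
    if path.suffix.lower() in (".csv", ".tsv"):
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        frame = pd.read_csv(path, sep=sep)
        if "smiles" not in frame.columns:
            raise InputError("compound table needs a 'smiles' column")
        if "compound_id" not in frame.columns:
            frame.insert(0, "compound_id", [f"CMP{i}" for i in range(len(frame))])
        return frame
    records = []
    for i, line in enumerate(path.read_text().splitlines()):
        parts = line.split()
        if not parts:
            continue
        records.append(
            {"compound_id": parts[1] if len(parts) > 1 else f"CMP{i}", "smiles": parts[0]}
        )
    if not records:
        raise InputError(f"no SMILES found in {path}")
    return pd.DataFrame(records)
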
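"""166-bit MACCS substructure fingerprints for drug molecules.

The MACCS key definitions are an external standard (MDL); bit semantics
are delegated to RDKit rather than re-implemented pattern by pattern.
RDKit emits 167 bits with a dummy bit 0 — that dummy is dropped so the
emitted vector is keys 1-166 in order. Precomputed fingerprint tables can
be loaded instead, decoupling the pipeline from any one chemistry toolkit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

from .errors import InputError, ParseError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

N_BITS = 166


@dataclass(frozen=True)
class DrugFingerprint:
    """A 166-bit substructure presence/absence vector for one drug."""

    bits: np.ndarray
    drug_id: str
    source: str = "computed"  # or "loaded"

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.int8)
        if bits.shape != (N_BITS,):
            raise InputError(
                f"fingerprint for {self.drug_id!r} has length {bits.size}, expected {N_BITS}"
            )
        if not np.isin(bits, (0, 1)).all():
            raise InputError(f"fingerprint for {self.drug_id!r} has non-binary entries")
        object.__setattr__(self, "bits", bits)


def fingerprint_molecule(
    mol: Chem.Mol, drug_id: str = "", allow_empty: bool = False
) -> DrugFingerprint:
    """MACCS fingerprint of an RDKit molecule (keys 1-166)."""
    if mol is None:
        raise InputError(f"molecule {drug_id!r} is not a valid structure")
    if mol.GetNumAtoms() == 0:
        if not allow_empty:
            raise InputError(f"molecule {drug_id!r} has no atoms")
        return DrugFingerprint(bits=np.zeros(N_BITS, dtype=np.int8), drug_id=drug_id)
    fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    bits = np.zeros(N_BITS, dtype=np.int8)
    for b in fp.GetOnBits():
        if b >= 1:
            bits[b - 1] = 1
    return DrugFingerprint(bits=bits, drug_id=drug_id)


def fingerprint_smiles(smiles: str, drug_id: str = "", allow_empty: bool = False) -> DrugFingerprint:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES for {drug_id!r}: {smiles!r}")
    return fingerprint_molecule(mol, drug_id=drug_id, allow_empty=allow_empty)


def fingerprints_from_smiles_file(
    path: str | Path, allow_empty: bool = False
) -> tuple[dict[str, DrugFingerprint], list[tuple[str, str]]]:
    """Read an ``id<TAB>smiles`` file; unparsable records are collected,
    not fatal. Returns (fingerprints, failures as (id, reason))."""
    fps: dict[str, DrugFingerprint] = {}
    failures: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'id<TAB>smiles', got {line!r}")
            drug_id, smiles = parts
            try:
                fps[drug_id] = fingerprint_smiles(smiles, drug_id, allow_empty=allow_empty)
            except InputError as exc:
                failures.append((drug_id, str(exc)))
    if failures:
        logger.warning("%d molecule(s) failed to fingerprint: %s",
                       len(failures), [f[0] for f in failures])
    return fps, failures


def fingerprints_from_sdf(
    path: str | Path, id_property: str = "_Name", allow_empty: bool = False
) -> tuple[dict[str, DrugFingerprint], list[tuple[str, str]]]:
    """Fingerprint every record of an SDF file."""
    fps: dict[str, DrugFingerprint] = {}
    failures: list[tuple[str, str]] = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            failures.append((f"record {i}", "unparsable SDF record"))
            continue
        drug_id = mol.GetProp(id_property) if mol.HasProp(id_property) else f"record {i}"
        try:
            fps[drug_id] = fingerprint_molecule(mol, drug_id, allow_empty=allow_empty)
        except InputError as exc:
            failures.append((drug_id, str(exc)))
    return fps, failures


def load_fingerprint_table(path: str | Path) -> dict[str, DrugFingerprint]:
    """Read a TSV of drug_id + 166 binary columns into fingerprints."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        logger.warning("fingerprint table %s is empty", path)
        return {}
    if df.empty and df.shape[1] == 0:
        logger.warning("fingerprint table %s is empty", path)
        return {}
    if df.shape[1] != N_BITS:
        raise ParseError(
            f"{path}: expected {N_BITS} fingerprint columns, got {df.shape[1]}"
        )
    fps: dict[str, DrugFingerprint] = {}
    for drug_id, row in df.iterrows():
        values = row.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            raise ParseError(
                f"{path}: non-binary entry {values[bad][0]!r} in row {drug_id!r}"
            )
        fps[str(drug_id)] = DrugFingerprint(
            bits=values.astype(np.int8), drug_id=str(drug_id), source="loaded"
        )
    return fps


def write_fingerprint_table(fps: dict[str, DrugFingerprint], path: str | Path) -> None:
    df = pd.DataFrame(
        {drug_id: fp.bits for drug_id, fp in fps.items()},
        index=[f"maccs{k}" for k in range(1, N_BITS + 1)],
    ).T
    df.index.name = "drug_id"
    df.to_csv(path, sep="\t")
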
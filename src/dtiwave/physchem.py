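"""Physicochemical encoding of protein sequences.

Each residue of a target sequence is replaced by six scalar property
values — hydrophobicity (H), side-chain volume (VSC), polarity (P1),
polarizability (P2), solvent-accessible surface area (SASA) and the net
charge index of the side chain (NCISC) — z-scored over the 20-letter
amino-acid alphabet. A sequence of length L therefore becomes an L x 6
signal matrix, one channel per property, which downstream modules treat
as a multi-channel discrete signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, DegenerateScaleError, InputError, ParseError

logger = logging.getLogger(__name__)

#: Fixed channel order; feature indices downstream depend on it.
PROPERTY_NAMES = ("H", "VSC", "P1", "P2", "SASA", "NCISC")

#: Row order of the packaged property table (alphabetical one-letter codes).
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity/rare-residue substitutions used by the "map" policy. X has no
#: defensible representative and is dropped even under "map".
_NEAREST = {"B": "N", "Z": "Q", "J": "L", "U": "C", "O": "K"}


@dataclass(frozen=True)
class PhysicochemicalTable:
    """The 20 x 6 amino-acid property matrix and its column z-scored form.

    ``ddof`` records the standard-deviation convention used for the
    normalization: 0 treats the 20-letter alphabet as the full population
    (the default — the alphabet is finite and fixed), 1 uses the sample SD.
    """

    raw_values: pd.DataFrame
    normalized_values: pd.DataFrame
    property_names: tuple[str, ...] = PROPERTY_NAMES
    amino_acid_order: tuple[str, ...] = AMINO_ACIDS
    ddof: int = 0
    _row_lookup: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        lookup = {
            aa: self.normalized_values.loc[aa].to_numpy(dtype=float)
            for aa in self.amino_acid_order
        }
        object.__setattr__(self, "_row_lookup", lookup)

    def row(self, residue: str) -> np.ndarray:
        return self._row_lookup[residue]


def load_raw_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read a property table CSV (packaged one by default).

    Expected layout: an ``amino_acid`` index column plus the six property
    columns, 20 rows.
    """
    if path is None:
        src = resources.files("dtiwave.data") / "aa_properties.csv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p, index_col="amino_acid")
    else:
        df = pd.read_csv(path, index_col="amino_acid")
    if df.shape != (20, 6):
        raise ConfigurationError(
            f"property table must be 20 amino acids x 6 properties, got {df.shape}"
        )
    if list(df.columns) != list(PROPERTY_NAMES):
        raise ConfigurationError(
            f"property columns must be {PROPERTY_NAMES} in order, got {tuple(df.columns)}"
        )
    if not all(aa in df.index for aa in AMINO_ACIDS):
        missing = sorted(set(AMINO_ACIDS) - set(df.index))
        raise ConfigurationError(f"property table missing amino acids: {missing}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"non-numeric entry in property table: {exc}") from exc
    if df.isna().any().any():
        raise ParseError("property table contains missing entries")
    return df.loc[list(AMINO_ACIDS)]


def normalize_property_table(
    raw: pd.DataFrame | None = None, ddof: int = 0
) -> PhysicochemicalTable:
    """Column-wise z-score the raw property table.

    normalized[i, j] = (raw[i, j] - mean_j) / sd_j, where the mean and SD
    are taken over the 20 amino-acid types of property j.
    """
    if raw is None:
        raw = load_raw_table()
    if raw.shape != (20, 6):
        raise ConfigurationError(
            f"property table must be 20 x 6, got {raw.shape}"
        )
    values = raw.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    degenerate = np.flatnonzero(sd == 0.0)
    if degenerate.size:
        cols = [raw.columns[i] for i in degenerate]
        raise DegenerateScaleError(
            f"zero-variance property column(s) cannot be z-scored: {cols}"
        )
    normalized = pd.DataFrame(
        (values - mean) / sd, index=raw.index, columns=raw.columns
    )
    return PhysicochemicalTable(raw_values=raw, normalized_values=normalized, ddof=ddof)


def default_table(ddof: int = 0) -> PhysicochemicalTable:
    """The packaged property table, normalized."""
    return normalize_property_table(load_raw_table(), ddof=ddof)


def sanitize_sequence(sequence: str, policy: str = "drop") -> str:
    """Uppercase, strip whitespace/digits, and resolve non-standard residues.

    Policies for residues outside the 20-letter alphabet:

    - ``drop``: remove them (logged);
    - ``map``: substitute a chemically similar standard residue where one
      exists (B->N, Z->Q, J->L, U->C, O->K), drop otherwise;
    - ``error``: raise :class:`InputError`.
    """
    if policy not in ("drop", "map", "error"):
        raise ConfigurationError(f"unknown residue policy {policy!r}")
    standard = set(AMINO_ACIDS)
    out = []
    dropped = []
    for ch in sequence.upper():
        if ch.isspace() or ch.isdigit() or ch in "*-.":
            continue
        if ch in standard:
            out.append(ch)
        elif policy == "map" and ch in _NEAREST:
            out.append(_NEAREST[ch])
        elif policy == "error":
            raise InputError(f"non-standard residue {ch!r} in sequence")
        else:
            dropped.append(ch)
    if dropped:
        logger.warning(
            "dropped %d non-standard residue(s): %s",
            len(dropped),
            "".join(sorted(set(dropped))),
        )
    return "".join(out)


@dataclass(frozen=True)
class SequenceSignalMatrix:
    """An L x 6 numeric encoding of one protein sequence."""

    values: np.ndarray
    sequence_id: str = ""

    @property
    def length(self) -> int:
        return self.values.shape[0]


def encode_sequence(
    sequence: str,
    table: PhysicochemicalTable | None = None,
    sequence_id: str = "",
    policy: str = "drop",
) -> SequenceSignalMatrix:
    """Translate an amino-acid string into its L x 6 property signal matrix.

    Row i is the normalized-table row of residue i; channel order is fixed
    to (H, VSC, P1, P2, SASA, NCISC).
    """
    if table is None:
        table = default_table()
    clean = sanitize_sequence(sequence, policy=policy)
    if not clean:
        raise InputError(
            f"sequence {sequence_id or sequence!r} is empty after sanitization"
        )
    values = np.stack([table.row(aa) for aa in clean])
    return SequenceSignalMatrix(values=values, sequence_id=sequence_id)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (record id, sequence string) from a multi-record FASTA file."""
    for record in SeqIO.parse(str(path), "fasta"):
        yield record.id, str(record.seq)


def encode_fasta(
    path: str | Path,
    table: PhysicochemicalTable | None = None,
    policy: str = "drop",
) -> dict[str, SequenceSignalMatrix]:
    """Encode every record of a FASTA file; keys are record IDs."""
    if table is None:
        table = default_table()
    return {
        rid: encode_sequence(seq, table, sequence_id=rid, policy=policy)
        for rid, seq in read_fasta(path)
    }
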
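"""Bipartite drug-target interaction network and its profile features.

The interaction network is an n_d x n_t binary adjacency over ordered
drug/target registries. The "net" feature of a pair (D_i, T_j) is the
interaction profile of D_i over all targets except T_j concatenated with
the profile of T_j over all drugs except D_i — a (n_t - 1) + (n_d - 1)
binary vector. During cross-validation the profiles must be computed
from a network whose held-out positive edges have been masked, otherwise
the feature encodes the test label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, UnknownIDError


@dataclass
class InteractionNetwork:
    """Bipartite adjacency with stable ID registries.

    Registry order follows the source file's first-appearance order so
    profile indices are reproducible across runs.
    """

    drug_ids: list[str]
    target_ids: list[str]
    adjacency: np.ndarray
    _drug_index: dict[str, int] = field(default_factory=dict, repr=False)
    _target_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        adj = np.asarray(self.adjacency)
        if adj.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ConfigurationError(
                f"adjacency shape {adj.shape} does not match registries "
                f"({len(self.drug_ids)} x {len(self.target_ids)})"
            )
        if not np.isin(adj, (0, 1)).all():
            raise ConfigurationError("adjacency entries must be 0 or 1")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ConfigurationError("duplicate drug IDs")
        if len(set(self.target_ids)) != len(self.target_ids):
            raise ConfigurationError("duplicate target IDs")
        self.adjacency = adj.astype(np.int8)
        self._drug_index = {d: i for i, d in enumerate(self.drug_ids)}
        self._target_index = {t: j for j, t in enumerate(self.target_ids)}

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_interactions(self) -> int:
        return int(self.adjacency.sum())

    def drug_index(self, drug_id: str) -> int:
        try:
            return self._drug_index[drug_id]
        except KeyError:
            raise UnknownIDError(f"unknown drug ID {drug_id!r}") from None

    def target_index(self, target_id: str) -> int:
        try:
            return self._target_index[target_id]
        except KeyError:
            raise UnknownIDError(f"unknown target ID {target_id!r}") from None

    def positives(self) -> list[tuple[str, str]]:
        """All known interacting (drug_id, target_id) pairs, row-major."""
        di, tj = np.nonzero(self.adjacency)
        return [(self.drug_ids[i], self.target_ids[j]) for i, j in zip(di, tj)]

    def unknown_pairs(self) -> list[tuple[str, str]]:
        """All pairs not known to interact, row-major."""
        di, tj = np.nonzero(self.adjacency == 0)
        return [(self.drug_ids[i], self.target_ids[j]) for i, j in zip(di, tj)]

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(
            drug_ids=list(self.drug_ids),
            target_ids=list(self.target_ids),
            adjacency=self.adjacency.copy(),
        )


@dataclass(frozen=True)
class NetFeature:
    """Interaction-profile feature of one (drug, target) pair."""

    drug_profile: np.ndarray   # length n_t - 1, query target's column removed
    target_profile: np.ndarray  # length n_d - 1, query drug's row removed

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.drug_profile, self.target_profile])


def net_feature(network: InteractionNetwork, drug_id: str, target_id: str) -> NetFeature:
    """Profile feature of (drug, target): the drug's row without the query
    target's column, then the target's column without the query drug's row."""
    i = network.drug_index(drug_id)
    j = network.target_index(target_id)
    drug_profile = np.delete(network.adjacency[i, :], j)
    target_profile = np.delete(network.adjacency[:, j], i)
    return NetFeature(drug_profile=drug_profile, target_profile=target_profile)


def net_feature_length(network: InteractionNetwork) -> int:
    return (network.n_drugs - 1) + (network.n_targets - 1)


def mask_test_edges(
    network: InteractionNetwork, test_pairs: list[tuple[str, str]]
) -> InteractionNetwork:
    """Copy of the network with the given pairs' edges zeroed.

    Training-fold net features are computed from this masked network so the
    held-out labels cannot leak through the profiles.
    """
    masked = network.copy()
    for drug_id, target_id in test_pairs:
        i = masked.drug_index(drug_id)
        j = masked.target_index(target_id)
        masked.adjacency[i, j] = 0
    return masked


def from_edge_list(
    path: str | Path,
    drug_ids: list[str] | None = None,
    target_ids: list[str] | None = None,
) -> InteractionNetwork:
    """Build a network from a ``drug_id<TAB>target_id`` edge list.

    Registries default to first-appearance order in the file; pass explicit
    ID lists to include interaction-free drugs/targets (e.g. the IDs of the
    fingerprint table and FASTA file).
    """
    fixed_registries = drug_ids is not None and target_ids is not None
    drug_ids = list(drug_ids) if drug_ids is not None else []
    target_ids = list(target_ids) if target_ids is not None else []
    drug_seen = set(drug_ids)
    target_seen = set(target_ids)
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'drug<TAB>target', got {line!r}")
            d, t = parts
            if d not in drug_seen:
                if fixed_registries:
                    raise ParseError(f"{path}:{lineno}: drug {d!r} not in supplied registry")
                drug_ids.append(d)
                drug_seen.add(d)
            if t not in target_seen:
                if fixed_registries:
                    raise ParseError(f"{path}:{lineno}: target {t!r} not in supplied registry")
                target_ids.append(t)
                target_seen.add(t)
            edges.append((d, t))
    adj = np.zeros((len(drug_ids), len(target_ids)), dtype=np.int8)
    di = {d: i for i, d in enumerate(drug_ids)}
    ti = {t: j for j, t in enumerate(target_ids)}
    for d, t in edges:
        adj[di[d], ti[t]] = 1
    return InteractionNetwork(drug_ids=drug_ids, target_ids=target_ids, adjacency=adj)


def from_adjacency(path: str | Path, orientation: str = "targets_x_drugs") -> InteractionNetwork:
    """Read a full adjacency-matrix TSV.

    The gold-standard distribution ships matrices with target rows and drug
    columns (``targets_x_drugs``, the default); ``drugs_x_targets`` reads
    the transpose convention.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "targets_x_drugs":
        df = df.T
    elif orientation != "drugs_x_targets":
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ParseError(f"{path}: adjacency entries must be 0/1")
    return InteractionNetwork(
        drug_ids=[str(x) for x in df.index],
        target_ids=[str(x) for x in df.columns],
        adjacency=values.astype(np.int8),
    )


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for d, t in network.positives():
            fh.write(f"{d}\t{t}\n")
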
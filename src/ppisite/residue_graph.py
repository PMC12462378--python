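"""Residue-graph construction for interaction-site prediction.

A protein chain becomes an undirected graph G(X, E, A): nodes are residues
located at their side-chain centroid (mean of side-chain heavy atoms; the
alpha carbon for glycine and side-chain-less residues), edges connect residue
pairs whose centroids lie within a distance cutoff (14 A by default), and each
node carries a 62-dimensional feature vector assembled from five precomputed
blocks (PSSM 20, HMM profile 20, DSSP 14, atomic properties 5, centered
centroid coordinates 3).  A 1024-d protein-language-model embedding can stand
in for the handcrafted blocks.

Producing the feature blocks (PSI-BLAST, HHblits, DSSP, ProtT5) is out of
scope; this module reads them from delimited tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

DEFAULT_CUTOFF = 14.0  # Angstrom, side-chain-centroid distance
SEQ_SEP_CAP = 64  # sequence-separation saturation for edge features
GRAPH_FORMAT_VERSION = 1

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class GraphFormatError(ValueError):
    """Raised when an on-disk graph container does not match the schema."""


@dataclass
class FeatureBundle:
    """The five handcrafted per-residue feature blocks (widths 20/20/14/5/3)."""

    pssm: np.ndarray
    hmm: np.ndarray
    dssp: np.ndarray
    atomic: np.ndarray
    pef: np.ndarray

    _WIDTHS = {"pssm": 20, "hmm": 20, "dssp": 14, "atomic": 5, "pef": 3}

    def __post_init__(self):
        n = None
        for name, width in self._WIDTHS.items():
            block = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, block)
            if block.ndim != 2 or block.shape[1] != width:
                raise ValueError(
                    f"feature block '{name}' must have width {width}, "
                    f"got shape {block.shape}"
                )
            if n is None:
                n = block.shape[0]
            elif block.shape[0] != n:
                raise ValueError(
                    f"feature block '{name}' has {block.shape[0]} rows, "
                    f"expected {n}"
                )

    @property
    def n_residues(self) -> int:
        return self.pssm.shape[0]

    def blocks(self):
        return [self.pssm, self.hmm, self.dssp, self.atomic, self.pef]


@dataclass
class ResidueGraph:
    """One protein chain as a spatial residue graph.

    ``edge_index`` lists both directions of every adjacent ordered pair
    (including self-pairs); ``edge_features`` aligns with it row-for-row.
    Residue order is chain sequence order — the pattern metrics depend on it.
    """

    node_features: np.ndarray  # [n, d_node]
    coords: np.ndarray  # [n, 3] Angstrom
    edge_index: np.ndarray  # [2, n_edges] int
    edge_features: np.ndarray  # [n_edges, d_edge]
    ids: list[str]
    name: str = ""
    labels: np.ndarray | None = None  # [n] 0/1, optional
    cutoff: float = DEFAULT_CUTOFF
    meta: dict = field(default_factory=dict)

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        """Dense symmetric boolean adjacency reconstructed from edge_index."""
        n = self.n_residues
        adj = np.zeros((n, n), dtype=bool)
        adj[self.edge_index[0], self.edge_index[1]] = True
        return adj

    def validate(self) -> None:
        n = self.n_residues
        if self.node_features.shape[0] != n or len(self.ids) != n:
            raise ValueError("node_features/ids length mismatch with coords")
        if not np.isfinite(self.node_features).all():
            raise ValueError("node_features contain non-finite entries")
        adj = self.adjacency
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency is not symmetric")
        if not adj.diagonal().all():
            raise ValueError("adjacency must include self-pairs")
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != (n,) or not np.isin(labels, (0, 1)).all():
                raise ValueError("labels must be a 0/1 vector of length n")


# ---------------------------------------------------------------------------
# PDB reading


def read_pdb_centroids(pdb_path, chain: str):
    """Extract side-chain centroids for one chain of a PDB file.

    Returns ``(coords, ids)``: one 3-vector per residue (mean of side-chain
    heavy atoms, falling back to the alpha carbon when none exist) in
    ascending residue-number order, insertion codes after their base number.
    Residues with no resolvable atoms at all are skipped with a warning.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("protein", str(pdb_path))
    model = next(structure.get_models())
    chain_ids = [c.id for c in model]
    if chain not in chain_ids:
        raise KeyError(f"chain not found: {chain!r} (available: {chain_ids})")

    entries = []
    for residue in model[chain]:
        hetflag, resseq, icode = residue.id
        if hetflag.strip():  # skip waters/het groups
            continue
        heavy = [a for a in residue if a.element != "H"]
        if not heavy:
            warnings.warn(
                f"residue {resseq}{icode.strip()} has no resolvable atoms; skipped"
            )
            continue
        side = [a for a in heavy if a.get_name() not in BACKBONE_ATOMS]
        if side:
            centroid = np.mean([a.coord for a in side], axis=0)
        elif "CA" in residue:
            centroid = np.asarray(residue["CA"].coord, dtype=float)
        else:
            centroid = np.mean([a.coord for a in heavy], axis=0)
        rid = f"{resseq}{icode.strip()}"
        entries.append((resseq, icode, rid, np.asarray(centroid, dtype=float)))

    if not entries:
        raise ValueError(f"chain {chain!r} contains no residues with atoms")
    entries.sort(key=lambda e: (e[0], e[1]))
    coords = np.stack([e[3] for e in entries])
    ids = [e[2] for e in entries]
    return coords, ids


# ---------------------------------------------------------------------------
# Graph construction


def build_adjacency(coords: np.ndarray, cutoff: float = DEFAULT_CUTOFF):
    """Cutoff adjacency: adjacent iff centroid distance strictly below cutoff.

    Self-pairs are always included (distance 0 < cutoff).  Returns the dense
    boolean adjacency and the full distance matrix.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"coords must be [n x 3], got {coords.shape}")
    bad = np.flatnonzero(~np.isfinite(coords).all(axis=1))
    if bad.size:
        raise ValueError(f"non-finite coordinates at residue index {bad[0]}")
    dist = cdist(coords, coords)
    adjacency = dist < cutoff
    return adjacency, dist


def build_edge_features(
    coords: np.ndarray,
    adjacency: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    sep_cap: int = SEQ_SEP_CAP,
):
    """Per-edge features for every adjacent ordered pair.

    Each edge (i, j) carries [distance/cutoff, min(|i-j|, sep_cap)/sep_cap];
    both components lie in [0, 1], the feature is symmetric in (i, j), and
    self-pairs get [0, 0].  Returns ``(edge_index [2 x E], edge_features
    [E x 2])`` with both directions listed.
    """
    coords = np.asarray(coords, dtype=float)
    adjacency = np.asarray(adjacency, dtype=bool)
    src, dst = np.nonzero(adjacency)
    edge_index = np.stack([src, dst])
    dist = np.linalg.norm(coords[src] - coords[dst], axis=1)
    sep = np.abs(src - dst)
    feats = np.stack(
        [dist / cutoff, np.minimum(sep, sep_cap) / sep_cap], axis=1
    )
    feats[src == dst] = 0.0
    return edge_index, feats


def minmax_normalize(matrix: np.ndarray) -> np.ndarray:
    """Column-wise min-max scaling to [0, 1]; constant columns map to 0."""
    matrix = np.asarray(matrix, dtype=float)
    lo = matrix.min(axis=0)
    hi = matrix.max(axis=0)
    span = hi - lo
    out = np.zeros_like(matrix)
    varying = span > 0
    out[:, varying] = (matrix[:, varying] - lo[varying]) / span[varying]
    return out


def assemble_node_features(bundle: FeatureBundle) -> np.ndarray:
    """Concatenate [pssm | hmm | dssp | atomic | pef] and min-max normalize
    per column (per protein).  Output width is exactly 62."""
    raw = np.concatenate(bundle.blocks(), axis=1)
    assert raw.shape[1] == 62
    return minmax_normalize(raw)


def build_graph(
    coords: np.ndarray,
    node_features: np.ndarray,
    ids: list[str] | None = None,
    labels: np.ndarray | None = None,
    name: str = "",
    cutoff: float = DEFAULT_CUTOFF,
) -> ResidueGraph:
    """Assemble a validated ResidueGraph from coordinates and node features."""
    coords = np.asarray(coords, dtype=float)
    node_features = np.asarray(node_features, dtype=float)
    adjacency, _ = build_adjacency(coords, cutoff)
    edge_index, edge_features = build_edge_features(coords, adjacency, cutoff)
    if ids is None:
        ids = [str(i + 1) for i in range(coords.shape[0])]
    graph = ResidueGraph(
        node_features=node_features,
        coords=coords,
        edge_index=edge_index,
        edge_features=edge_features,
        ids=list(ids),
        name=name,
        labels=None if labels is None else np.asarray(labels, dtype=int),
        cutoff=cutoff,
    )
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# Tabular input

_BLOCK_PREFIXES = ("pssm", "hmm", "dssp", "atomic", "pef")


def read_feature_table(path):
    """Read a per-residue feature TSV into node-feature input.

    Columns are named ``<block>_<k>`` for the five handcrafted blocks, or
    ``plm_<k>`` for a protein-language-model embedding.  Returns either a
    FeatureBundle (handcrafted) or a raw [n x d] array (embedding).
    """
    table = pd.read_csv(path, sep="\t")
    columns = list(table.columns)
    if any(c.startswith("plm_") for c in columns):
        plm_cols = [c for c in columns if c.startswith("plm_")]
        return table[plm_cols].to_numpy(dtype=float)
    blocks = {}
    for prefix in _BLOCK_PREFIXES:
        cols = [c for c in columns if c.startswith(prefix + "_")]
        cols.sort(key=lambda c: int(c.rsplit("_", 1)[1]))
        if not cols:
            raise ValueError(f"feature table missing block '{prefix}'")
        blocks[prefix] = table[cols].to_numpy(dtype=float)
    return FeatureBundle(**blocks)


def read_labels(path) -> tuple[list[str], np.ndarray]:
    """Read a two-column TSV (residue id, 0/1 label) in sequence order."""
    table = pd.read_csv(path, sep="\t", header=None, names=["id", "label"])
    labels = table["label"].to_numpy(dtype=int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return table["id"].astype(str).tolist(), labels


# ---------------------------------------------------------------------------
# On-disk container


def save_graph(graph: ResidueGraph, path) -> None:
    """Write a ResidueGraph to a single-file npz container with JSON header."""
    header = {
        "format_version": GRAPH_FORMAT_VERSION,
        "cutoff": graph.cutoff,
        "d_node": int(graph.node_features.shape[1]),
        "name": graph.name,
        "has_labels": graph.labels is not None,
    }
    arrays = {
        "header": np.frombuffer(
            json.dumps(header).encode("utf-8"), dtype=np.uint8
        ),
        "node_features": graph.node_features,
        "coords": graph.coords,
        "edge_index": graph.edge_index,
        "edge_features": graph.edge_features,
        "ids": np.array(graph.ids, dtype="U32"),
    }
    if graph.labels is not None:
        arrays["labels"] = np.asarray(graph.labels, dtype=np.int64)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_graph(path) -> ResidueGraph:
    """Load a graph container written by :func:`save_graph`."""
    try:
        with np.load(path, allow_pickle=False) as data:
            arrays = {key: data[key] for key in data.files}
    except Exception as exc:  # truncated / not an npz
        raise GraphFormatError(f"cannot read graph container: {exc}") from exc
    required = {"header", "node_features", "coords", "edge_index", "edge_features", "ids"}
    missing = required - set(arrays)
    if missing:
        raise GraphFormatError(f"graph container missing arrays: {sorted(missing)}")
    try:
        header = json.loads(arrays["header"].tobytes().decode("utf-8"))
    except Exception as exc:
        raise GraphFormatError(f"unreadable graph header: {exc}") from exc
    version = header.get("format_version")
    if version != GRAPH_FORMAT_VERSION:
        raise GraphFormatError(
            f"unsupported graph format_version {version!r} "
            f"(expected {GRAPH_FORMAT_VERSION})"
        )
    graph = ResidueGraph(
        node_features=arrays["node_features"],
        coords=arrays["coords"],
        edge_index=arrays["edge_index"],
        edge_features=arrays["edge_features"],
        ids=[str(s) for s in arrays["ids"]],
        name=header.get("name", ""),
        labels=arrays["labels"] if "labels" in arrays else None,
        cutoff=float(header.get("cutoff", DEFAULT_CUTOFF)),
    )
    graph.validate()
    return graph
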
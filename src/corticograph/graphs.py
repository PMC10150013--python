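"""Channel-graph assembly and the 12-class sub-action label space.

A segment becomes one undirected graph: 40 nodes (32 EEG + 8 EMG channels,
each with a length-7 spectral feature vector) and edges given by the
strongest quarter of pairwise SPMI values.  EEG and EMG nodes share one
feature schema and one edge semantics — heterogeneity is representational
only, so any general-purpose GNN can consume the graphs.

Sub-action labels combine the movement and the segment position:
class = movement_block * 6 + position, with push occupying classes 0-5 and
pull 6-11 (fixed, arbitrary ordering).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import connectivity as conn
from . import node_features as nf
from .preprocessing import SegmentWindow
from .synthetic_data import (EEG_CHANNEL_NAMES, EMG_CHANNEL_NAMES, MOVEMENTS)

__all__ = [
    "ChannelGraph",
    "N_SUBACTIONS",
    "build_graph",
    "encode_label",
    "decode_label",
    "save_graphs",
    "load_graphs",
    "graph_to_json",
]

N_POSITIONS = 6
N_SUBACTIONS = len(MOVEMENTS) * N_POSITIONS  # 12
ALL_CHANNEL_NAMES = EEG_CHANNEL_NAMES + EMG_CHANNEL_NAMES


def encode_label(movement: str, position: int) -> int:
    """(movement, position) -> class index 0..11; push block first."""
    if movement not in MOVEMENTS:
        raise ValueError(f"unknown movement {movement!r}")
    if not 0 <= position < N_POSITIONS:
        raise ValueError(f"position must be in 0..{N_POSITIONS - 1}, got {position}")
    return MOVEMENTS.index(movement) * N_POSITIONS + position


def decode_label(index: int) -> tuple[str, int]:
    """Inverse of :func:`encode_label`."""
    if not 0 <= index < N_SUBACTIONS:
        raise ValueError(f"class index must be in 0..{N_SUBACTIONS - 1}, got {index}")
    return MOVEMENTS[index // N_POSITIONS], index % N_POSITIONS


@dataclass
class ChannelGraph:
    """One labeled graph instance: the GNN input."""

    node_features: np.ndarray   # (40, 7)
    edges: np.ndarray           # (E, 2) int, i < j, no self-loops/duplicates
    movement: str
    position: int
    subject_id: str = ""
    group: str = "healthy"
    channel_names: list[str] = field(default_factory=lambda: list(ALL_CHANNEL_NAMES))

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        n = self.node_features.shape[0]
        if self.edges.size:
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("graph contains self-loops")
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ValueError("edge references a nonexistent node")
            canon = np.sort(self.edges, axis=1)
            if len({(i, j) for i, j in map(tuple, canon)}) != len(canon):
                raise ValueError("graph contains duplicate edges")

    @property
    def subaction_class(self) -> int:
        return encode_label(self.movement, self.position)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


def build_graph(
    segment: SegmentWindow,
    ordinal_cfg: conn.OrdinalConfig | None = None,
    band_scheme: nf.BandScheme | None = None,
    q: float = 0.25,
) -> ChannelGraph:
    """Segment window -> labeled channel graph.

    Node features come from the multitaper band fractions (EEG channels are
    referenced to the 2-40 Hz filter band, EMG channels to 2-100 Hz, each
    modality's own totality); edges from thresholded all-pairs SPMI.
    """
    ordinal_cfg = ordinal_cfg or conn.OrdinalConfig(degenerate_as_zero=True)
    band_scheme = band_scheme or nf.DEFAULT_BANDS
    feats = np.stack([
        nf.node_feature(
            segment.data[ch], electrode_index=ch, rate=segment.rate,
            scheme=band_scheme,
            total_band=(nf.EEG_TOTAL_BAND if ch < segment.n_eeg
                        else nf.EMG_TOTAL_BAND),
        )
        for ch in range(segment.n_channels)
    ])
    names = (ALL_CHANNEL_NAMES if segment.n_channels == len(ALL_CHANNEL_NAMES)
             else [f"ch{i}" for i in range(segment.n_channels)])
    matrix = conn.spmi_matrix(segment.data, ordinal_cfg, channel_names=names)
    edges = conn.threshold_edges(matrix, q)
    return ChannelGraph(
        node_features=feats, edges=edges, movement=segment.movement,
        position=segment.position, subject_id=segment.subject_id,
        group=segment.group, channel_names=names,
    )


def save_graphs(graphs: list[ChannelGraph], path) -> None:
    """One HDF5 file for a whole graph set (ragged edges via offsets)."""
    path = Path(path)
    feats = np.stack([g.node_features for g in graphs])
    counts = np.array([len(g.edges) for g in graphs])
    offsets = np.concatenate([[0], np.cumsum(counts)])
    edge_index = (np.concatenate([g.edges for g in graphs])
                  if len(graphs) else np.zeros((0, 2), dtype=np.int64))
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        f.create_dataset("node_features", data=feats)
        f.create_dataset("edge_index", data=edge_index)
        f.create_dataset("edge_offsets", data=offsets)
        f.create_dataset("movement", data=[g.movement for g in graphs], dtype=str_dt)
        f.create_dataset("position", data=[g.position for g in graphs])
        f.create_dataset("subject_id", data=[g.subject_id for g in graphs], dtype=str_dt)
        f.create_dataset("group", data=[g.group for g in graphs], dtype=str_dt)


def load_graphs(path) -> list[ChannelGraph]:
    with h5py.File(path, "r") as f:
        feats = f["node_features"][()]
        edge_index = f["edge_index"][()]
        offsets = f["edge_offsets"][()]
        movement = [m.decode() for m in f["movement"][()]]
        position = f["position"][()]
        subject = [s.decode() for s in f["subject_id"][()]]
        group = [s.decode() for s in f["group"][()]]
    return [
        ChannelGraph(
            node_features=feats[i],
            edges=edge_index[offsets[i]:offsets[i + 1]],
            movement=movement[i], position=int(position[i]),
            subject_id=subject[i], group=group[i],
        )
        for i in range(feats.shape[0])
    ]


def graph_to_json(graph: ChannelGraph) -> str:
    """Human-readable per-graph debug dump."""
    return json.dumps({
        "movement": graph.movement,
        "position": graph.position,
        "subaction_class": graph.subaction_class,
        "subject_id": graph.subject_id,
        "group": graph.group,
        "n_nodes": graph.n_nodes,
        "n_edges": int(len(graph.edges)),
        "node_features": graph.node_features.tolist(),
        "edges": graph.edges.tolist(),
        "channel_names": graph.channel_names,
    }, indent=2)
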
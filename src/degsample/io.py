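"""File formats: TSV edge lists, weights tables, GraphML, run manifests."""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__

__all__ = [
    "RunManifest",
    "read_edge_list",
    "write_edge_list",
    "write_samples",
    "read_weights",
    "write_weights",
    "read_observables",
    "write_graphml",
    "write_manifest",
]

Edge = tuple[int, int]


@dataclass
class RunManifest:
    """Enough metadata to reproduce a run bit-identically."""

    command: str
    parameters: dict
    seed: int | None
    version: str = __version__
    started: str = ""
    finished: str = ""

    def finish(self) -> "RunManifest":
        self.finished = datetime.now(timezone.utc).isoformat()
        return self

    @staticmethod
    def start(command: str, parameters: dict, seed: int | None) -> "RunManifest":
        return RunManifest(
            command=command,
            parameters=parameters,
            seed=seed,
            started=datetime.now(timezone.utc).isoformat(),
        )


def write_manifest(path: str | Path, manifest: RunManifest) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(manifest.finish()), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _canonical_edges(edges: Iterable[Edge]) -> list[Edge]:
    return sorted(tuple(sorted((int(u), int(v)))) for u, v in edges)


def write_edge_list(path: str | Path, edges: Iterable[Edge]) -> None:
    """Two-column TSV, 0-based labels, u < v per row, lexicographic rows."""
    with open(path, "w") as fh:
        fh.write("u\tv\n")
        for u, v in _canonical_edges(edges):
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path: str | Path) -> list[Edge]:
    df = pd.read_csv(path, sep="\t")
    return [(int(u), int(v)) for u, v in zip(df["u"], df["v"])]


def write_samples(path: str | Path, samples: Sequence) -> None:
    """Concatenated edge lists with a sample_id column."""
    with open(path, "w") as fh:
        fh.write("sample_id\tu\tv\n")
        for i, s in enumerate(samples):
            for u, v in _canonical_edges(s.edges):
                fh.write(f"{i}\t{u}\t{v}\n")


def write_weights(path: str | Path, samples: Sequence) -> None:
    """Companion weights TSV: sample_id, log_weight, seed."""
    with open(path, "w") as fh:
        fh.write("sample_id\tlog_weight\tseed\n")
        for i, s in enumerate(samples):
            seed = "" if s.seed is None else int(s.seed)
            fh.write(f"{i}\t{s.log_weight:.12g}\t{seed}\n")


def read_weights(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_observables(path: str | Path) -> pd.DataFrame:
    """TSV with columns sample_id, value."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: expected columns sample_id, value")
    return df


def write_graphml(path: str | Path, edges: Iterable[Edge], nodes: Iterable[int] | None = None) -> None:
    """Minimal GraphML export (undirected), re-importable by standard readers."""
    es = _canonical_edges(edges)
    node_set = set(nodes) if nodes is not None else set()
    for u, v in es:
        node_set.update((u, v))
    root = ET.Element("graphml", xmlns="http://graphml.graphdrawing.org/xmlns")
    g = ET.SubElement(root, "graph", id="G", edgedefault="undirected")
    for n in sorted(node_set):
        ET.SubElement(g, "node", id=f"n{n}")
    for u, v in es:
        ET.SubElement(g, "edge", source=f"n{u}", target=f"n{v}")
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
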
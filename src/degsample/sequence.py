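"""Degree sequences: normalization, labels, and the plain-text file format.

A degree sequence is kept internally in non-increasing order together with
the permutation back to the caller's original node labels.  Zero-degree
entries are stripped at construction (the sampling algorithm removes
exhausted nodes from the sequence) and reported separately as isolated
nodes, to be re-attached by output routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DegreeSequence",
    "normalize_sequence",
    "read_degree_sequence",
    "write_degree_sequence",
]


@dataclass(frozen=True)
class DegreeSequence:
    """A labeled degree sequence in non-increasing order.

    Attributes
    ----------
    values
        Positive degrees, non-increasing.  Values larger than ``n - 1`` are
        permitted: the sequence may be non-graphical and is only *tested*
        for graphicality downstream.
    labels
        ``labels[i]`` is the original node label of the degree at sorted
        position ``i`` (a bijection onto the nonzero-degree labels).
    isolated
        Original labels whose input degree was zero.
    """

    values: np.ndarray
    labels: np.ndarray
    isolated: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.int64))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int64))
        object.__setattr__(self, "isolated", np.asarray(self.isolated, dtype=np.int64))
        v = self.values
        if v.size and np.any(v[:-1] < v[1:]):
            raise ValueError("degree values must be non-increasing")
        if np.any(v < 1):
            raise ValueError("degree values must be positive (zeros are stripped)")
        if self.labels.size != v.size:
            raise ValueError("labels and values must have equal length")

    @property
    def n(self) -> int:
        """Number of nonzero-degree nodes."""
        return int(self.values.size)

    @property
    def degree_sum(self) -> int:
        return int(self.values.sum())

    def degree_of(self) -> dict[int, int]:
        """Mapping original label -> degree (nonzero entries only)."""
        return {int(l): int(d) for l, d in zip(self.labels, self.values)}

    def __iter__(self):
        return iter(self.values.tolist())

    def __len__(self) -> int:
        return self.n


def normalize_sequence(
    raw: Iterable[int], labels: Sequence[int] | None = None
) -> DegreeSequence:
    """Sort degrees into non-increasing order, recording the label permutation.

    Zero entries are dropped and their labels reported via
    :attr:`DegreeSequence.isolated`.  Ties between equal degrees keep
    ascending original-label order (stable).

    Raises
    ------
    ValueError
        If any entry is negative.
    """
    d = np.asarray(list(raw), dtype=np.int64)
    if d.ndim != 1:
        raise ValueError("expected a flat sequence of integers")
    if np.any(d < 0):
        raise ValueError("degrees must be non-negative")
    if labels is None:
        lab = np.arange(d.size, dtype=np.int64)
    else:
        lab = np.asarray(list(labels), dtype=np.int64)
        if lab.size != d.size:
            raise ValueError("labels must match the number of degrees")
        if np.unique(lab).size != lab.size:
            raise ValueError("labels must be distinct")
    isolated = lab[d == 0]
    keep = d > 0
    d, lab = d[keep], lab[keep]
    # np.lexsort is stable: secondary key label ascending, primary degree desc.
    order = np.lexsort((lab, -d))
    return DegreeSequence(values=d[order], labels=lab[order], isolated=isolated)


def read_degree_sequence(path: str | Path) -> DegreeSequence:
    """Read whitespace/newline-separated non-negative integers.

    Lines starting with ``#`` are ignored.  Node labels are the 0-based
    positions of the entries in file order (zeros included).
    """
    degrees: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            for tok in stripped.split():
                try:
                    val = int(tok)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: invalid degree token {tok!r}"
                    ) from None
                if val < 0:
                    raise ValueError(f"{path}:{lineno}: negative degree {val}")
                degrees.append(val)
    return normalize_sequence(degrees)


def write_degree_sequence(path: str | Path, seq: DegreeSequence | Iterable[int]) -> None:
    """Write a degree sequence, one integer per line, in original label order.

    Accepts either a :class:`DegreeSequence` (restores original label order,
    isolated nodes written as zeros) or any iterable of degrees (written as
    given).
    """
    if isinstance(seq, DegreeSequence):
        all_labels = np.concatenate([seq.labels, seq.isolated])
        out = np.zeros(all_labels.max() + 1 if all_labels.size else 0, dtype=np.int64)
        out[seq.labels] = seq.values
        values = out.tolist()
    else:
        values = [int(v) for v in seq]
    with open(path, "w") as fh:
        for v in values:
            fh.write(f"{v}\n")
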
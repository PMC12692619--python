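"""k-of-n residue-overlap consensus of multi-tool epitope predictions.

A residue is consensus-supported when at least ``k`` of the ``n`` predictors
cover it with at least one interval (duplicate intervals from the same tool
count once).  Maximal supported runs form consensus epitopes; runs shorter
than ``min_len`` are discarded.  This residue-level semantics reproduces the
textbook worked example — tools predicting ABCDEFG and CDEFGH share the
common segment CDEFG — and, unlike pairwise interval intersection, also
handles regions stitched together by different supporting pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import ProteinRecord

Interval = tuple[int, int]


@dataclass(frozen=True)
class ToolPrediction:
    """One predictor's interval set (1-based inclusive, need not be disjoint)."""

    tool: str
    intervals: tuple

    def __init__(self, tool: str, intervals) -> None:
        object.__setattr__(self, "tool", tool)
        object.__setattr__(
            self, "intervals",
            tuple(sorted((int(s), int(e)) for s, e in intervals)),
        )
        for start, end in self.intervals:
            if not 1 <= start <= end:
                raise ValueError(
                    f"tool {tool!r}: invalid interval {start}..{end}"
                )


@dataclass(frozen=True)
class ConsensusConfig:
    k: int = 2          # minimum supporting tools per residue
    n: int = 3          # number of tools combined
    min_len: int = 5    # minimum consensus region length

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.n:
            raise ValueError(f"need 1 <= k <= n, got k={self.k}, n={self.n}")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass(frozen=True)
class ConsensusEpitope:
    """A maximal run of residues supported by >= k tools."""

    start: int
    end: int
    support: frozenset
    peptide: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid region {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def as_tuple(self) -> Interval:
        return (self.start, self.end)


def residue_support(predictions: list[ToolPrediction],
                    length: int) -> np.ndarray:
    """Per-position count of distinct tools covering each residue.

    Index 0 of the returned vector is residue 1.
    """
    counts = np.zeros(length, dtype=int)
    for pred in predictions:
        covered = np.zeros(length, dtype=bool)
        for start, end in pred.intervals:
            if not (1 <= start <= end <= length):
                raise ValueError(
                    f"tool {pred.tool!r}: interval {start}..{end} outside "
                    f"sequence of length {length}"
                )
            covered[start - 1 : end] = True
        counts += covered
    return counts


def consensus_regions(predictions: list[ToolPrediction],
                      config: ConsensusConfig, length: int,
                      sequence: ProteinRecord | None = None,
                      ) -> list[ConsensusEpitope]:
    """Maximal runs of residues with support >= k, filtered by min_len."""
    support = residue_support(predictions, length)
    mask = support >= config.k
    regions = []
    start = None
    for i, flag in enumerate(list(mask) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            s, e = start + 1, i
            if e - s + 1 >= config.min_len:
                tools = frozenset(
                    p.tool for p in predictions
                    if any(iv_s <= e and iv_e >= s
                           for iv_s, iv_e in p.intervals)
                )
                peptide = sequence.slice(s, e) if sequence is not None else ""
                regions.append(ConsensusEpitope(s, e, tools, peptide))
            start = None
    return regions


def extract_peptides(sequence: ProteinRecord,
                     epitopes: list) -> list[tuple[Interval, str]]:
    """Attach residue strings to intervals (1-based inclusive)."""
    out = []
    for ep in epitopes:
        start, end = ep.as_tuple() if hasattr(ep, "as_tuple") else tuple(ep)
        out.append(((start, end), sequence.slice(start, end)))
    return out
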
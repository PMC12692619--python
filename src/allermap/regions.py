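"""Convert per-residue tracks into candidate epitope intervals.

Selection follows the classical multi-criterion rule for linear B-cell
epitopes: positive hydrophilicity, positive antigenic index, surface
probability above 1, flexibility above the average-mobility baseline of 1,
optionally restricted to turn/coil residues.  Residues passing every enabled
criterion form maximal runs; runs shorter than ``min_len`` are dropped and
runs longer than ``max_len`` are split recursively at their weakest
antigenic-index position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bepipred import ScoreProfile
from .propensity import ResidueProfile
from .secstruct import SSAssignment


@dataclass(frozen=True)
class CallCriteria:
    """Residue-wise thresholds, all strict inequalities."""

    hydrophilicity_min: float = 0.0
    antigenic_index_min: float = 0.0
    surface_min: float = 1.0
    flexibility_min: float = 1.0
    require_ss_states: frozenset = frozenset()  # subset of {"T", "C"}
    min_len: int = 5
    max_len: int = 30

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")
        if not set(self.require_ss_states) <= {"T", "C"}:
            raise ValueError("require_ss_states must be a subset of {T, C}")


@dataclass(frozen=True)
class EpitopeInterval:
    """A 1-based inclusive candidate epitope interval."""

    start: int
    end: int
    tool: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def as_tuple(self) -> tuple[int, int]:
        return (self.start, self.end)


def mask_to_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as 1-based inclusive intervals."""
    runs = []
    start = None
    for i, flag in enumerate(list(mask) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start + 1, i))
            start = None
    return runs


def _split_long(run: tuple[int, int], ai: np.ndarray, max_len: int,
                ) -> list[tuple[int, int]]:
    """Split a too-long run at its weakest antigenic-index residue,
    recursing until every piece respects max_len."""
    start, end = run
    if end - start + 1 <= max_len:
        return [run]
    window = ai[start - 1 : end]
    weakest = start + int(np.nanargmin(window))  # 1-based position removed
    pieces = []
    if weakest - 1 >= start:
        pieces.extend(_split_long((start, weakest - 1), ai, max_len))
    if weakest + 1 <= end:
        pieces.extend(_split_long((weakest + 1, end), ai, max_len))
    return pieces


def call_regions_multi(hydrophilicity: ResidueProfile,
                       antigenic_index: ResidueProfile,
                       surface: ResidueProfile,
                       flexibility: ResidueProfile,
                       ss: SSAssignment | None = None,
                       criteria: CallCriteria | None = None,
                       tool: str = "profile-suite") -> list[EpitopeInterval]:
    """Residue-wise AND of all enabled criteria, then run extraction.

    NaN track values (undefined window positions) never pass.  Requires the
    four named tracks; ``ss`` may be omitted only when ``require_ss_states``
    is empty.
    """
    criteria = criteria or CallCriteria()
    tracks = {
        "hydrophilicity": hydrophilicity,
        "antigenic_index": antigenic_index,
        "surface": surface,
        "flexibility": flexibility,
    }
    for name, track in tracks.items():
        if track is None:
            raise ValueError(f"missing required track: {name}")
    lengths = {len(t) for t in tracks.values()}
    if ss is not None:
        lengths.add(len(ss.states))
    if len(lengths) != 1:
        raise ValueError(f"track length mismatch: {sorted(lengths)}")
    n = lengths.pop()

    with np.errstate(invalid="ignore"):
        mask = (
            (hydrophilicity.values > criteria.hydrophilicity_min)
            & (antigenic_index.values > criteria.antigenic_index_min)
            & (surface.values > criteria.surface_min)
            & (flexibility.values > criteria.flexibility_min)
        )
    if criteria.require_ss_states:
        if ss is None:
            raise ValueError("missing required track: secondary structure")
        mask &= np.isin(list(ss.states), sorted(criteria.require_ss_states))

    intervals = []
    for run in mask_to_runs(mask):
        for start, end in _split_long(run, antigenic_index.values,
                                      criteria.max_len):
            if end - start + 1 >= criteria.min_len:
                mean_ai = float(np.nanmean(
                    antigenic_index.values[start - 1 : end]))
                intervals.append(EpitopeInterval(start, end, tool, mean_ai))
    return intervals


def call_regions_threshold(score: ScoreProfile,
                           threshold: float | None = None,
                           min_len: int = 5,
                           tool: str = "bepipred-like",
                           ) -> list[EpitopeInterval]:
    """Maximal runs with score strictly above the threshold, length >= min_len."""
    if len(score) == 0:
        raise ValueError("empty score profile")
    thr = score.threshold if threshold is None else threshold
    with np.errstate(invalid="ignore"):
        mask = score.values > thr
    out = []
    for start, end in mask_to_runs(mask):
        if end - start + 1 >= min_len:
            out.append(EpitopeInterval(
                start, end, tool,
                float(np.mean(score.values[start - 1 : end]))))
    return out


def merge_adjacent(intervals: list, max_gap: int = 0) -> list[tuple[int, int]]:
    """Union intervals whose separating gap (count of uncovered residues
    between them) is <= max_gap.  [1,5] and [6,9] have a gap of 0 and merge;
    [1,5] and [8,9] have a gap of 2.  Output is sorted and disjoint."""
    tuples = sorted(
        iv.as_tuple() if isinstance(iv, EpitopeInterval) else tuple(iv)
        for iv in intervals
    )
    if not tuples:
        return []
    merged = [tuples[0]]
    for start, end in tuples[1:]:
        last_start, last_end = merged[-1]
        if start - last_end - 1 <= max_gap:
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged
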
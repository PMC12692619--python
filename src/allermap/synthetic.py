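"""Deterministic generators for pipeline testing.

Two generators cover the two halves of the pipeline: protein sequences with
planted hydrophilic/flexible/coil-prone segments (the statistical signature
the epitope-selection criteria reward), and multi-tool interval sets derived
from a known truth by boundary jitter, drop-out and false positives.  All
output is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bepipred import bepipred_like_profile, train_two_state
from .consensus import ConsensusConfig, ToolPrediction, consensus_regions
from .propensity import (
    emini_profile,
    jameson_wolf_profile,
    karplus_schulz_profile,
    windowed_mean_profile,
)
from .regions import CallCriteria, call_regions_multi, call_regions_threshold
from .scales import SCALE_HOPP_WOODS, SCALE_PARKER
from .secstruct import chou_fasman, gor, ss_consensus
from .seqio import STANDARD_AA, ProteinRecord

#: Residues enriched inside planted segments: hydrophilic (K, E, D),
#: flexible/coil-prone (G, S, P).
EPITOPE_ALPHABET_WEIGHTS = {
    "K": 4.0, "E": 4.0, "D": 4.0, "G": 3.0, "S": 3.0, "P": 2.0,
    "N": 2.0, "Q": 2.0, "R": 2.0, "T": 1.0,
}


@dataclass(frozen=True)
class PlantSpec:
    """A synthetic protein: background sequence with planted segments."""

    length: int = 100
    segments: tuple = ((30, 44), (70, 81))
    seed: int = 42
    bias: dict = field(default_factory=lambda: dict(EPITOPE_ALPHABET_WEIGHTS))

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        prev_end = 0
        for start, end in sorted(self.segments):
            if not (1 <= start <= end <= self.length):
                raise ValueError(
                    f"segment {start}..{end} outside length {self.length}"
                )
            if start <= prev_end:
                raise ValueError(f"segments overlap at {start}..{end}")
            prev_end = end


@dataclass(frozen=True)
class JitterSpec:
    """How tool predictions are perturbed away from the truth."""

    boundary_jitter: int = 0     # +- residues on each boundary
    fp_rate: float = 0.0         # expected false intervals per 100 residues
    drop_prob: float = 0.0       # per-tool, per-interval drop probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_jitter < 0:
            raise ValueError("boundary_jitter must be >= 0")
        if not 0.0 <= self.fp_rate <= 1.0:
            raise ValueError("fp_rate must lie in [0, 1]")
        if not 0.0 <= self.drop_prob <= 1.0:
            raise ValueError("drop_prob must lie in [0, 1]")


def _weights(bias: dict) -> np.ndarray:
    w = np.array([bias.get(aa, 0.5) for aa in STANDARD_AA])
    return w / w.sum()


def generate_protein(spec: PlantSpec) -> tuple[ProteinRecord,
                                               list[tuple[int, int]]]:
    """Background from uniform residue weights; planted segments from the
    biased alphabet.  Bit-reproducible for a given (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(STANDARD_AA))
    residues = rng.choice(alphabet, size=spec.length)
    biased = _weights(spec.bias)
    for start, end in spec.segments:
        residues[start - 1 : end] = rng.choice(
            alphabet, size=end - start + 1, p=biased)
    record = ProteinRecord(
        id=f"synthetic-{spec.seed}",
        residues="".join(residues),
        description=f"synthetic protein, {len(spec.segments)} planted segments",
    )
    return record, sorted(spec.segments)


def generate_tool_predictions(truth: list[tuple[int, int]], length: int,
                              jitter: JitterSpec | None = None,
                              n_tools: int = 3) -> list[ToolPrediction]:
    """Per-tool copies of the truth with jittered boundaries, drop-outs and
    false-positive intervals."""
    jitter = jitter or JitterSpec()
    for start, end in truth:
        if not (1 <= start <= end <= length):
            raise ValueError(f"truth interval {start}..{end} outside length {length}")
    rng = np.random.default_rng(jitter.seed)
    tools = []
    for t in range(n_tools):
        intervals = []
        for start, end in truth:
            if rng.random() < jitter.drop_prob:
                continue
            j = jitter.boundary_jitter
            if j:
                start = start + int(rng.integers(-j, j + 1))
                end = end + int(rng.integers(-j, j + 1))
            start = max(1, min(start, length))
            end = max(start, min(end, length))
            intervals.append((start, end))
        n_fp = rng.poisson(jitter.fp_rate * length / 100.0)
        for _ in range(n_fp):
            fp_len = int(rng.integers(5, 13))
            fp_start = int(rng.integers(1, max(2, length - fp_len + 2)))
            intervals.append((fp_start, min(length, fp_start + fp_len - 1)))
        tools.append(ToolPrediction(f"tool-{t + 1}", intervals))
    return tools


@dataclass(frozen=True)
class RecoveryReport:
    """Residue-level agreement between consensus output and planted truth."""

    precision: float
    recall: float
    tool_recalls: tuple
    consensus: tuple
    truth: tuple


def _coverage(intervals, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for start, end in intervals:
        mask[start - 1 : end] = True
    return mask


def _precision_recall(predicted: np.ndarray, truth: np.ndarray,
                      ) -> tuple[float, float]:
    tp = np.count_nonzero(predicted & truth)
    precision = tp / predicted.sum() if predicted.any() else 1.0
    recall = tp / truth.sum() if truth.any() else 1.0
    return precision, recall


def _profile_pipeline_tools(record: ProteinRecord,
                            truth: list[tuple[int, int]],
                            min_len: int) -> list[ToolPrediction]:
    """Three real scoring routes: profile-suite calling, turn/coil runs and
    a trained two-state scorer."""
    hydro = windowed_mean_profile(record, SCALE_HOPP_WOODS)
    surface = emini_profile(record)
    flex = karplus_schulz_profile(record)
    ss = ss_consensus([chou_fasman(record), gor(record)])
    ai = jameson_wolf_profile(hydro, surface, flex, ss)
    suite = call_regions_multi(hydro, ai, surface, flex, ss,
                               CallCriteria(min_len=min_len))

    coil_mask = np.isin(list(ss.states), ["T", "C"])
    from .regions import mask_to_runs
    coil_calls = [iv for iv in mask_to_runs(coil_mask)
                  if iv[1] - iv[0] + 1 >= min_len]

    model = train_two_state([(record, truth)])
    parker = windowed_mean_profile(record, SCALE_PARKER)
    score = bepipred_like_profile(record, model, parker)
    scored = call_regions_threshold(score, min_len=min_len)

    return [
        ToolPrediction("profile-suite", [iv.as_tuple() for iv in suite]),
        ToolPrediction("sopma-like", coil_calls),
        ToolPrediction("bepipred-like", [iv.as_tuple() for iv in scored]),
    ]


def end_to_end_recovery(spec: PlantSpec,
                        jitter: JitterSpec | None = None,
                        config: ConsensusConfig | None = None,
                        mode: str = "intervals") -> RecoveryReport:
    """Generate a protein, derive three tool predictions, run the consensus
    and score residue-level precision/recall against the planted truth.

    ``mode="intervals"`` (default) derives the tools from the truth via
    :func:`generate_tool_predictions` — with zero jitter this round-trip is
    lossless for segments of at least ``min_len`` residues.
    ``mode="profiles"`` runs the actual scoring pipelines (profile suite,
    turn/coil calling, trained two-state scorer); no recovery guarantee
    holds there, which is the realistic situation.
    """
    config = config or ConsensusConfig()
    record, truth = generate_protein(spec)
    if mode == "intervals":
        tools = generate_tool_predictions(truth, len(record), jitter)
    elif mode == "profiles":
        tools = _profile_pipeline_tools(record, truth, config.min_len)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    regions = consensus_regions(tools, config, len(record), sequence=record)
    truth_mask = _coverage(truth, len(record))
    cons_mask = _coverage([r.as_tuple() for r in regions], len(record))
    precision, recall = _precision_recall(cons_mask, truth_mask)
    tool_recalls = tuple(
        _precision_recall(_coverage(t.intervals, len(record)), truth_mask)[1]
        for t in tools
    )
    return RecoveryReport(
        precision=precision,
        recall=recall,
        tool_recalls=tool_recalls,
        consensus=tuple(r.as_tuple() for r in regions),
        truth=tuple(truth),
    )
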
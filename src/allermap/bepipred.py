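"""BepiPred-1.0-style per-residue epitope scoring.

A two-state (epitope / background) hidden Markov model supplies a posterior
epitope probability per residue via forward-backward; this is mixed with a
standardised Parker hydrophilicity track.  The published tool's trained
weights are not distributed, so the model here is re-estimated from labelled
sequences (supervised counting with add-one smoothing); its interval output
is interchangeable with externally supplied interval sets everywhere
downstream.  The conventional decision threshold of 0.35 is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .propensity import ResidueProfile
from .seqio import STANDARD_AA, ProteinRecord

EPITOPE, BACKGROUND = 0, 1
DEFAULT_THRESHOLD = 0.35

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


@dataclass
class TwoStateModel:
    """Emissions (2 x 20), transitions (2 x 2) and the mixing weight w."""

    emissions: np.ndarray
    transitions: np.ndarray
    mixing_weight: float = 0.5

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.emissions.shape != (2, len(STANDARD_AA)):
            raise ValueError("emissions must be 2 x 20")
        if self.transitions.shape != (2, 2):
            raise ValueError("transitions must be 2 x 2")
        for name, rows in (("emission", self.emissions),
                           ("transition", self.transitions)):
            sums = rows.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1, got {sums}")
        if not 0.0 <= self.mixing_weight <= 1.0:
            raise ValueError("mixing_weight must lie in [0, 1]")

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the transition matrix (initial probs)."""
        evals, evecs = np.linalg.eig(self.transitions.T)
        k = int(np.argmin(np.abs(evals - 1.0)))
        pi = np.real(evecs[:, k])
        return pi / pi.sum()

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps({
            "alphabet": STANDARD_AA,
            "states": ["epitope", "background"],
            "emissions": self.emissions.tolist(),
            "transitions": self.transitions.tolist(),
            "mixing_weight": self.mixing_weight,
        }, indent=1)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "TwoStateModel":
        if isinstance(source, Path) or (len(str(source)) < 4096
                                        and Path(str(source)).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = json.loads(text)
        return cls(np.array(doc["emissions"]), np.array(doc["transitions"]),
                   doc["mixing_weight"])


@dataclass
class ScoreProfile:
    """Per-residue epitope score with its decision threshold."""

    values: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    method: str = "bepipred-like"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def _label_mask(record: ProteinRecord,
                intervals: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(len(record), dtype=bool)
    for start, end in intervals:
        if not (1 <= start <= end <= len(record)):
            raise ValueError(
                f"interval {start}..{end} outside record {record.id!r} "
                f"of length {len(record)}"
            )
        mask[start - 1 : end] = True
    return mask


def train_two_state(labeled: list[tuple[ProteinRecord, list[tuple[int, int]]]],
                    mixing_weight: float = 0.5) -> TwoStateModel:
    """Supervised re-estimation from interval-labelled sequences.

    Emissions are add-one-smoothed residue counts per state; transitions are
    add-one-smoothed counts of consecutive label pairs.  The result depends
    only on the aggregate counts, not on sequence order.
    """
    if not labeled:
        raise ValueError("need at least one labelled sequence")
    emis = np.ones((2, len(STANDARD_AA)))  # add-one smoothing
    trans = np.ones((2, 2))
    for record, intervals in labeled:
        mask = _label_mask(record, intervals)
        states = np.where(mask, EPITOPE, BACKGROUND)
        for aa, st in zip(record.residues, states):
            if aa != "X":
                emis[st, _AA_INDEX[aa]] += 1
        for a, b in zip(states[:-1], states[1:]):
            trans[a, b] += 1
    emis /= emis.sum(axis=1, keepdims=True)
    trans /= trans.sum(axis=1, keepdims=True)
    return TwoStateModel(emis, trans, mixing_weight)


def _emission_column(model: TwoStateModel, aa: str) -> np.ndarray:
    if aa == "X":
        return np.array([1.0, 1.0])  # uninformative observation
    return model.emissions[:, _AA_INDEX[aa]]


def posterior_profile(record: ProteinRecord, model: TwoStateModel,
                      ) -> ScoreProfile:
    """Forward-backward posterior probability of the epitope state.

    The chain is initialised at the stationary distribution of the
    transition matrix, so uninformative (identical) emissions give a flat
    posterior equal to the stationary epitope probability.
    """
    n = len(record)
    b = np.stack([_emission_column(model, aa) for aa in record.residues])
    trans = model.transitions
    alpha = np.zeros((n, 2))
    scale = np.zeros(n)
    alpha[0] = model.stationary() * b[0]
    scale[0] = alpha[0].sum()
    if scale[0] == 0:
        raise ValueError("zero-probability observation at position 1")
    alpha[0] /= scale[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ trans) * b[t]
        scale[t] = alpha[t].sum()
        if scale[t] == 0:
            raise ValueError(f"zero-probability observation at position {t + 1}")
        alpha[t] /= scale[t]
    beta = np.ones((n, 2))
    for t in range(n - 2, -1, -1):
        beta[t] = (trans @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return ScoreProfile(gamma[:, EPITOPE], method="hmm-posterior")


def standardize(values: np.ndarray) -> np.ndarray:
    """Per-sequence z-standardisation (zero vector if the track is constant)."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def bepipred_like_profile(record: ProteinRecord, model: TwoStateModel,
                          parker_track: ResidueProfile,
                          threshold: float = DEFAULT_THRESHOLD) -> ScoreProfile:
    """Mixed epitope score: w*(2*posterior - 1) + (1 - w)*z(parker).

    The posterior is affinely rescaled to [-1, 1] so both components are
    centred; the decision threshold (default 0.35) is applied downstream by
    interval calling.
    """
    if len(parker_track) != len(record):
        raise ValueError(
            f"track length {len(parker_track)} != sequence length {len(record)}"
        )
    post = posterior_profile(record, model).values
    w = model.mixing_weight
    score = w * (2.0 * post - 1.0) + (1.0 - w) * standardize(parker_track.values)
    return ScoreProfile(score, threshold=threshold)
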
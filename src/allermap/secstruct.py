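"""Secondary-structure prediction over four states: H, E, T, C.

Two classical single-sequence predictors are provided: the Chou-Fasman
nucleation/extension algorithm and a GOR-style directional-information
summation.  The GOR-style predictor uses the "allermap-dr1" parameter set,
a *derived* (synthetic) table built from single-residue conformational
propensities with a triangular distance decay — it follows the GOR
functional form (summed information values over a 17-residue window) but is
not a transcription of the original experimentally derived table, and no
claim of numerical parity with published GOR servers is made.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .scales import CF_COIL, CF_HELIX, CF_SHEET, CF_TURN, CF_TURN_F
from .seqio import STANDARD_AA, ProteinRecord

STATES = "HETC"


@dataclass(frozen=True)
class SSAssignment:
    """Per-residue secondary-structure states over {H, E, T, C}."""

    method: str
    states: str

    def __post_init__(self) -> None:
        bad = set(self.states) - set(STATES)
        if bad:
            raise ValueError(f"invalid secondary-structure symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class SSFractions:
    helix: float
    sheet: float
    turn: float
    coil: float

    def __post_init__(self) -> None:
        total = self.helix + self.sheet + self.turn + self.coil
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class GORConfig:
    """Window geometry and parameter-set identifier for the GOR-style method."""

    half_window: int = 8  # total window 17
    parameter_table_id: str = "allermap-dr1"

    def __post_init__(self) -> None:
        if self.half_window < 1:
            raise ValueError("half_window must be >= 1")


_STATE_PROPENSITY = {"H": CF_HELIX, "E": CF_SHEET, "T": CF_TURN, "C": CF_COIL}


def _build_gor_table(half_window: int) -> dict:
    """Directional information values for the derived allermap-dr1 set.

    info[state][residue][offset] for offsets -half_window..+half_window;
    the self-information 10*ln(P/100) is attenuated by a triangular decay
    with distance from the centre.
    """
    table: dict = {}
    span = half_window + 1
    for state, prop in _STATE_PROPENSITY.items():
        table[state] = {}
        for aa in STANDARD_AA:
            info0 = 10.0 * math.log(max(prop[aa], 1) / 100.0)
            table[state][aa] = {
                d: info0 * max(0.0, 1.0 - abs(d) / span)
                for d in range(-half_window, half_window + 1)
            }
    return table


_GOR_TABLES: dict = {}


def gor_information_table(config: GORConfig | None = None) -> dict:
    """Return (and cache) the directional information table for a config."""
    config = config or GORConfig()
    if config.parameter_table_id != "allermap-dr1":
        raise ValueError(
            f"unknown GOR parameter table {config.parameter_table_id!r}"
        )
    key = (config.parameter_table_id, config.half_window)
    if key not in _GOR_TABLES:
        _GOR_TABLES[key] = _build_gor_table(config.half_window)
    return _GOR_TABLES[key]


def gor(record: ProteinRecord, config: GORConfig | None = None) -> SSAssignment:
    """GOR-style prediction: per-residue argmax of summed directional
    information over the window; ties resolve to C."""
    config = config or GORConfig()
    table = gor_information_table(config)
    if not table:
        raise ValueError("empty GOR information table")
    n = len(record)
    seq = record.residues
    hw = config.half_window
    states = []
    for i in range(n):
        best_state, best_sum = "C", -math.inf
        for state in "HETC":
            total = 0.0
            sub = table[state]
            for d in range(-hw, hw + 1):
                j = i + d
                if 0 <= j < n:
                    aa = seq[j]
                    if aa == "X":
                        continue  # no information from unknown residues
                    total += sub[aa][d]
            # any tie for the maximum resolves to C
            if total > best_sum + 1e-12:
                best_state, best_sum = state, total
            elif abs(total - best_sum) <= 1e-12:
                best_state = "C"
        states.append(best_state)
    return SSAssignment(f"gor[{config.parameter_table_id}]", "".join(states))


def _mean_prop(seq: str, table: dict, lo: int, hi: int) -> float:
    vals = [table.get(aa, 100) for aa in seq[lo:hi]]
    return sum(vals) / len(vals)


def chou_fasman(record: ProteinRecord,
                helix_former_min: float = 100.0,
                sheet_former_min: float = 105.0,
                turn_product_min: float = 7.5e-5) -> SSAssignment:
    """Chou-Fasman prediction by nucleation and extension.

    Helix: nucleate where >= 4 of 6 consecutive residues are helix formers
    (P(helix) >= 100), extend while the 4-residue window mean stays >= 100.
    Sheet: nucleate where >= 3 of 5 are sheet formers (P(sheet) >= 105),
    extend while the mean stays >= 105.  Turn: a tetrapeptide at i is a turn
    when the positional bend-frequency product exceeds ``turn_product_min``
    and its mean turn propensity exceeds 100 and exceeds both helix and sheet
    means.  Overlapping helix/sheet stretches go to the higher mean
    propensity; turns override both; everything else is coil.
    """
    n = len(record)
    if n < 6:
        raise ValueError(f"Chou-Fasman requires length >= 6, got {n}")
    seq = record.residues

    def grow(mask_len: int, former: dict, former_min: float, need: int,
             window: int, ext_min: float) -> np.ndarray:
        region = np.zeros(n, dtype=bool)
        for i in range(n - window + 1):
            formers = sum(former.get(aa, 0) >= former_min
                          for aa in seq[i : i + window])
            if formers >= need:
                lo, hi = i, i + window
                while lo > 0 and _mean_prop(seq, former, lo - 1, lo + 3) >= ext_min:
                    lo -= 1
                while hi < n and _mean_prop(seq, former, hi - 3, hi + 1) >= ext_min:
                    hi += 1
                region[lo:hi] = True
        return region

    helix = grow(6, CF_HELIX, helix_former_min, 4, 6, 100.0)
    sheet = grow(5, CF_SHEET, sheet_former_min, 3, 5, 105.0)

    turn = np.zeros(n, dtype=bool)
    for i in range(n - 3):
        quad = seq[i : i + 4]
        if "X" in quad:
            continue
        product = 1.0
        for k, aa in enumerate(quad):
            product *= CF_TURN_F[k][aa]
        mean_t = _mean_prop(seq, CF_TURN, i, i + 4)
        if (product > turn_product_min and mean_t > 100.0
                and mean_t > _mean_prop(seq, CF_HELIX, i, i + 4)
                and mean_t > _mean_prop(seq, CF_SHEET, i, i + 4)):
            turn[i : i + 4] = True

    states = []
    for i in range(n):
        if turn[i]:
            states.append("T")
        elif helix[i] and sheet[i]:
            # overlap: the locally stronger propensity wins
            lo, hi = max(0, i - 2), min(n, i + 3)
            ph = _mean_prop(seq, CF_HELIX, lo, hi)
            pe = _mean_prop(seq, CF_SHEET, lo, hi)
            states.append("H" if ph >= pe else "E")
        elif helix[i]:
            states.append("H")
        elif sheet[i]:
            states.append("E")
        else:
            states.append("C")
    return SSAssignment("chou-fasman", "".join(states))


def ss_consensus(assignments: list[SSAssignment],
                 tie_policy: str = "C") -> SSAssignment:
    """Per-position majority vote across assignments; any tie for the top
    count resolves to ``tie_policy`` (default C)."""
    if not assignments:
        raise ValueError("need at least one assignment")
    lengths = {len(a) for a in assignments}
    if len(lengths) != 1:
        raise ValueError(f"assignment length mismatch: {sorted(lengths)}")
    if tie_policy not in STATES:
        raise ValueError(f"tie_policy must be one of {STATES}")
    out = []
    for column in zip(*(a.states for a in assignments)):
        counts = Counter(column)
        top = max(counts.values())
        leaders = [s for s in STATES if counts.get(s, 0) == top]
        out.append(leaders[0] if len(leaders) == 1 else tie_policy)
    return SSAssignment("consensus", "".join(out))


def state_fractions(a: SSAssignment) -> SSFractions:
    if len(a) == 0:
        raise ValueError("empty assignment")
    n = len(a)
    c = Counter(a.states)
    return SSFractions(
        helix=c.get("H", 0) / n,
        sheet=c.get("E", 0) / n,
        turn=c.get("T", 0) / n,
        coil=c.get("C", 0) / n,
    )


def coil_fraction_of_regions(a: SSAssignment,
                             intervals: list[tuple[int, int]],
                             include_turn: bool = False) -> float:
    """Fraction of residues inside the union of 1-based inclusive intervals
    that are coil (optionally coil-or-turn)."""
    if not intervals:
        raise ValueError("no epitope residues: empty interval list")
    n = len(a)
    member = np.zeros(n, dtype=bool)
    for start, end in intervals:
        if not (1 <= start <= end <= n):
            raise ValueError(f"interval {start}..{end} outside length-{n} assignment")
        member[start - 1 : end] = True
    wanted = {"C", "T"} if include_turn else {"C"}
    inside = [s for s, m in zip(a.states, member) if m]
    return sum(s in wanted for s in inside) / len(inside)
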
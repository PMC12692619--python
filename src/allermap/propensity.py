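"""Per-residue sliding-window profiles and the Jameson-Wolf antigenic index.

A :class:`ResidueProfile` carries one value per residue, 1-based-aligned to
its sequence.  Window positions that do not fit are either computed over the
truncated window (``edge_policy="shrink"``, the default, so interval calling
can reach the termini) or left NaN (``edge_policy="undefined"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scales import (
    EMINI,
    KARPLUS_SCHULZ,
    PropensityScale,
    SCALE_KARPLUS_SCHULZ,
)
from .seqio import ProteinRecord
from .secstruct import SSAssignment

#: Jameson-Wolf class values: each input track is discretised onto this ladder.
JW_CLASSES = (-0.6, -0.3, 0.0, 0.3, 0.6)

#: Jameson-Wolf weights: hydrophilicity, surface, flexibility, secondary structure.
JW_WEIGHTS = {"hydro": 0.3, "surface": 0.15, "flex": 0.15, "ss": 0.4}


@dataclass
class ResidueProfile:
    """A per-residue numeric track aligned 1-based to a sequence."""

    method: str
    window: int
    values: np.ndarray
    edge_policy: str = "shrink"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)

    def value_at(self, position: int) -> float:
        """Value at a 1-based residue position."""
        return float(self.values[position - 1])


def _lookup(seq: str, table: dict) -> np.ndarray:
    try:
        return np.array([table[aa] for aa in seq], dtype=float)
    except KeyError as exc:
        raise ValueError(f"no scale value for residue {exc.args[0]!r}") from None


def windowed_mean_profile(record: ProteinRecord, scale: PropensityScale,
                          window: int | None = None,
                          edge_policy: str = "shrink") -> ResidueProfile:
    """Sliding-window mean of a propensity scale, centred on each residue."""
    if window is None:
        window = scale.default_window
    n = len(record)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    if edge_policy not in ("shrink", "undefined"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")

    raw = _lookup(record.residues, scale.table)
    half = (window - 1) // 2
    values = np.full(n, np.nan)
    for i in range(n):
        lo, hi = i - half, i + half + 1
        if lo < 0 or hi > n:
            if edge_policy == "undefined":
                continue
            lo, hi = max(lo, 0), min(hi, n)
        values[i] = raw[lo:hi].mean()
    return ResidueProfile(scale.name, window, values, edge_policy)


def emini_profile(record: ProteinRecord,
                  edge_policy: str = "shrink") -> ResidueProfile:
    """Emini surface probability.

    For the hexapeptide starting at n the score is the product of the six
    residues' fractional surface probabilities times 0.37^-6, anchored at
    position n+2; values above 1 mark above-random surface probability.
    Under the shrink policy, terminal positions use the truncated window with
    a matching 0.37^-len normalisation.
    """
    n = len(record)
    if n < 6:
        raise ValueError(f"Emini profile requires length >= 6, got {n}")
    if edge_policy not in ("shrink", "undefined"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")

    raw = _lookup(record.residues, EMINI)
    values = np.full(n, np.nan)
    # hexapeptide starting at index i (0-based) -> anchor index i + 2
    for i in range(n - 5):
        values[i + 2] = np.prod(raw[i : i + 6]) * 0.37 ** -6
    if edge_policy == "shrink":
        for pos in (0, 1):  # truncated leading windows, anchored like n+2
            win = raw[: pos + 4]
            values[pos] = np.prod(win) * 0.37 ** -len(win)
        for pos in (n - 3, n - 2, n - 1):
            win = raw[pos - 2 :]
            values[pos] = np.prod(win) * 0.37 ** -len(win)
    return ResidueProfile("emini", 6, values, edge_policy)


def karplus_schulz_profile(record: ProteinRecord, window: int = 7,
                           edge_policy: str = "shrink") -> ResidueProfile:
    """Windowed mean of normalised B-factor propensities (1.0 = average)."""
    return windowed_mean_profile(record, SCALE_KARPLUS_SCHULZ, window,
                                 edge_policy)


def discretize_quintiles(profile: ResidueProfile) -> np.ndarray:
    """Map a track onto the five Jameson-Wolf classes by its own quintiles.

    The commercial implementation's absolute cutoffs are unpublished;
    per-sequence quantile cutoffs keep class occupancy stable across
    sequences of very different dynamic range.
    """
    vals = profile.values
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("profile has no finite values to discretise")
    qs = np.quantile(finite, [0.2, 0.4, 0.6, 0.8])
    idx = np.sum(vals[:, None] > qs[None, :], axis=1)
    classes = np.array(JW_CLASSES)[idx]
    classes[~np.isfinite(vals)] = np.nan
    return classes


def jameson_wolf_from_classes(h_cls: np.ndarray, s_cls: np.ndarray,
                              f_cls: np.ndarray, ss: SSAssignment,
                              ) -> np.ndarray:
    """Antigenic index from already-discretised class tracks.

    AI(i) = 0.3 h + 0.15 s + 0.15 f + 0.4 c with c = +0.6 for turn/coil and
    -0.6 for helix/sheet.  The original method's two separately weighted
    secondary-structure terms are collapsed into the single consensus term c.
    """
    lengths = {len(h_cls), len(s_cls), len(f_cls), len(ss.states)}
    if len(lengths) != 1:
        raise ValueError(f"track length mismatch: {sorted(lengths)}")
    c = np.where(np.isin(list(ss.states), ["T", "C"]), 0.6, -0.6)
    return (JW_WEIGHTS["hydro"] * np.asarray(h_cls)
            + JW_WEIGHTS["surface"] * np.asarray(s_cls)
            + JW_WEIGHTS["flex"] * np.asarray(f_cls)
            + JW_WEIGHTS["ss"] * c)


def jameson_wolf_profile(hydro: ResidueProfile, surface: ResidueProfile,
                         flex: ResidueProfile, ss: SSAssignment,
                         ) -> ResidueProfile:
    """Jameson-Wolf antigenic index from hydrophilicity, surface-probability
    and flexibility tracks plus a secondary-structure assignment."""
    lengths = {len(hydro), len(surface), len(flex), len(ss.states)}
    if len(lengths) != 1:
        raise ValueError(f"track length mismatch: {sorted(lengths)}")
    ai = jameson_wolf_from_classes(
        discretize_quintiles(hydro),
        discretize_quintiles(surface),
        discretize_quintiles(flex),
        ss,
    )
    return ResidueProfile("jameson-wolf", 1, ai, "shrink")
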
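"""Global physicochemical properties: GRAVY, molecular weight, pI, identity.

GRAVY (grand average of hydropathy) is the mean Kyte-Doolittle value over the
sequence; negative values indicate a hydrophilic protein.  The isoelectric
point is found by bisection on the Henderson-Hasselbalch net charge using a
fixed published pKa set (EMBOSS), recorded in :mod:`allermap.scales`.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner
from Bio.SeqUtils import molecular_weight as _bio_mw
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .scales import KYTE_DOOLITTLE, PKA_EMBOSS
from .seqio import ProteinRecord


@dataclass(frozen=True)
class PhyschemSummary:
    gravy: float
    molecular_weight: float
    isoelectric_point: float


def _require_no_x(record: ProteinRecord, what: str) -> None:
    if "X" in record.residues:
        pos = record.residues.index("X") + 1
        raise ValueError(
            f"record {record.id!r}: {what} undefined for X at position {pos}; "
            "remove or substitute ambiguous residues before computing"
        )


def gravy(record: ProteinRecord) -> float:
    """Mean Kyte-Doolittle hydropathy over all residues."""
    _require_no_x(record, "hydropathy")
    return ProteinAnalysis(record.residues).gravy()


def molecular_weight(record: ProteinRecord) -> float:
    """Average-isotope molecular weight in Da (residue masses + one water)."""
    _require_no_x(record, "molecular weight")
    return _bio_mw(record.residues, seq_type="protein")


def net_charge(record: ProteinRecord, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (EMBOSS pKa set)."""
    _require_no_x(record, "charge")
    pka = PKA_EMBOSS

    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10 ** (ph - pk))

    def neg(pk: float) -> float:
        return 1.0 / (1.0 + 10 ** (pk - ph))

    charge = pos(pka["Nterm"]) - neg(pka["Cterm"])
    for aa in record.residues:
        if aa in ("K", "R", "H"):
            charge += pos(pka[aa])
        elif aa in ("D", "E", "C", "Y"):
            charge -= neg(pka[aa])
    return charge


def isoelectric_point(record: ProteinRecord, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection to |charge| < tol."""
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(record, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def summarize(record: ProteinRecord) -> PhyschemSummary:
    return PhyschemSummary(
        gravy=gravy(record),
        molecular_weight=molecular_weight(record),
        isoelectric_point=isoelectric_point(record),
    )


def percent_identity(a: ProteinRecord, b: ProteinRecord,
                     mode: str = "global") -> float:
    """Percent identity under a substitution-free alignment scheme.

    Match +1, mismatch 0, gap -1 (open and extend); identity is counted over
    all alignment columns of the optimal alignment, so gap columns dilute the
    percentage.  ``mode`` is ``"global"`` (Needleman-Wunsch) or ``"local"``
    (Smith-Waterman).
    """
    if mode not in ("global", "local"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a.residues, b.residues)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return 0.0
    return 100.0 * counts.identities / columns


# Convenience re-export of the scale GRAVY is defined on.
GRAVY_SCALE = KYTE_DOOLITTLE
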
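"""Map epitope intervals onto predicted 3D structure models.

Models arrive as PDB or mmCIF files whose B-factor column holds per-residue
confidence (pLDDT for models from modern structure predictors).  Solvent
accessibility is computed with a deterministic Shrake-Rupley sampler (golden
spiral point set, probe 1.4 A); relative accessibility divides by a fixed
theoretical maximal-ASA table so an epitope can be called exposed at a
configurable RSA cutoff (default 0.25, a common convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .scales import MAX_ASA_THEORETICAL, VDW_RADII

log = logging.getLogger(__name__)

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960
DEFAULT_RSA_THRESHOLD = 0.25

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Residue:
    index: int          # 1-based author residue number
    name: str           # one-letter code, X for non-standard
    elements: tuple     # per-atom element symbols (hydrogens excluded)
    coords: np.ndarray  # (n_atoms, 3) in Angstrom
    bfactors: np.ndarray


@dataclass(frozen=True)
class StructureModel:
    chain_id: str
    residues: tuple

    def __post_init__(self) -> None:
        indices = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("residue indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def index_range(self) -> tuple[int, int]:
        return (self.residues[0].index, self.residues[-1].index)

    def residue_bfactor_means(self) -> np.ndarray:
        return np.array([r.bfactors.mean() for r in self.residues])


@dataclass(frozen=True)
class ModelQuality:
    """Whole-model confidence summary; pTM is pass-through metadata."""

    mean_plddt: float
    ptm: float | None = None


@dataclass(frozen=True)
class EpitopeStructureReport:
    interval: tuple[int, int]
    mean_rsa: float
    mean_plddt: float   # normalised to the 0-100 scale
    exposed: bool


def read_structure(path: str | Path, chain: str | None = None,
                   ) -> StructureModel:
    """Read the first model of a PDB/mmCIF file; hydrogens are dropped.

    ``chain`` selects a chain by id; by default the first chain containing
    protein residues is taken.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty structure file")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: cannot parse structure: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    if len(st) > 1:
        log.info("%s: %d models; using the first", path, len(st))
    model = st[0]

    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        residues = []
        for res in ch:
            elements, coords, bfs = [], [], []
            for atom in res:
                if atom.element.name.upper() == "H":
                    continue
                elements.append(atom.element.name.upper())
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                bfs.append(atom.b_iso)
            if not coords:
                continue
            xyz = np.array(coords)
            if not np.all(np.isfinite(xyz)):
                raise ValueError(
                    f"{path}: non-finite coordinates in residue "
                    f"{res.name} {res.seqid.num}"
                )
            residues.append(Residue(
                index=res.seqid.num,
                name=_THREE_TO_ONE.get(res.name, "X"),
                elements=tuple(elements),
                coords=xyz,
                bfactors=np.array(bfs),
            ))
        if residues and any(r.name != "X" for r in residues):
            return StructureModel(chain_id=ch.name, residues=tuple(residues))
    raise ValueError(f"{path}: no protein chain found"
                     + (f" with id {chain!r}" if chain else ""))


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform point set on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def shrake_rupley_sasa(model: StructureModel,
                       probe_radius: float = DEFAULT_PROBE_RADIUS,
                       n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-residue solvent-accessible surface area in A^2.

    Each atom's expanded sphere (vdw + probe) is sampled with the fixed
    golden-spiral point set; a sample point is accessible when it lies
    outside every neighbouring atom's expanded sphere.  Deterministic for a
    given model and n_points.
    """
    elements, coords, owner = [], [], []
    for ri, res in enumerate(model.residues):
        for el, xyz in zip(res.elements, res.coords):
            elements.append(el)
            coords.append(xyz)
            owner.append(ri)
    if not coords:
        raise ValueError("model has no atoms")
    unknown = sorted({el for el in elements if el not in VDW_RADII})
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s): {unknown}")

    xyz = np.asarray(coords)
    radii = np.array([VDW_RADII[el] for el in elements]) + probe_radius
    sphere = golden_spiral_points(n_points)
    tree = cKDTree(xyz)
    max_reach = 2.0 * radii.max()

    per_atom = np.zeros(len(xyz))
    for i in range(len(xyz)):
        neighbors = [j for j in tree.query_ball_point(xyz[i], radii[i] + max_reach)
                     if j != i]
        points = xyz[i] + radii[i] * sphere
        if neighbors:
            nb_xyz = xyz[neighbors]
            nb_r = radii[neighbors]
            d2 = ((points[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_r ** 2)[None, :]).any(axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = n_points
        per_atom[i] = 4.0 * np.pi * radii[i] ** 2 * accessible / n_points

    per_residue = np.zeros(len(model))
    for asa, ri in zip(per_atom, owner):
        per_residue[ri] += asa
    return per_residue


def relative_accessibility(asa: np.ndarray, residue_names: list[str],
                           ) -> np.ndarray:
    """RSA = ASA / theoretical maximal ASA for the residue type."""
    asa = np.asarray(asa, dtype=float)
    if len(asa) != len(residue_names):
        raise ValueError("ASA vector and residue list differ in length")
    out = np.zeros_like(asa)
    for i, (a, name) in enumerate(zip(asa, residue_names)):
        if name not in MAX_ASA_THEORETICAL:
            raise ValueError(
                f"no maximal-ASA reference for residue {name!r} at index {i}"
            )
        out[i] = a / MAX_ASA_THEORETICAL[name]
    return out


def _normalize_plddt(values: np.ndarray) -> np.ndarray:
    """Confidence values on a 0-1 scale are rescaled to 0-100."""
    values = np.asarray(values, dtype=float)
    if values.size and np.nanmax(values) <= 1.0:
        return values * 100.0
    return values


def model_quality(model: StructureModel, ptm: float | None = None,
                  ) -> ModelQuality:
    plddt = _normalize_plddt(model.residue_bfactor_means())
    return ModelQuality(mean_plddt=float(plddt.mean()), ptm=ptm)


def epitope_report(model: StructureModel,
                   epitopes: list[tuple[int, int]],
                   rsa_threshold: float = DEFAULT_RSA_THRESHOLD,
                   offset: int = 0,
                   probe_radius: float = DEFAULT_PROBE_RADIUS,
                   n_points: int = DEFAULT_N_POINTS,
                   ) -> list[EpitopeStructureReport]:
    """Mean RSA, mean pLDDT and an exposure call per epitope interval.

    ``offset`` shifts sequence coordinates onto model numbering (model
    residue number = sequence position + offset), for models built on the
    mature chain while epitopes are numbered on the full-length sequence or
    vice versa.
    """
    index_of = {res.index: i for i, res in enumerate(model.residues)}
    asa = shrake_rupley_sasa(model, probe_radius, n_points)
    rsa = relative_accessibility(asa, [r.name for r in model.residues])
    plddt = _normalize_plddt(model.residue_bfactor_means())

    reports = []
    for start, end in (ep.as_tuple() if hasattr(ep, "as_tuple") else tuple(ep)
                       for ep in epitopes):
        rows = []
        for pos in range(start + offset, end + offset + 1):
            if pos not in index_of:
                lo, hi = model.index_range
                raise ValueError(
                    f"epitope {start}..{end} (offset {offset}) needs model "
                    f"residue {pos}, outside model range {lo}..{hi}"
                )
            rows.append(index_of[pos])
        mean_rsa = float(rsa[rows].mean())
        reports.append(EpitopeStructureReport(
            interval=(start, end),
            mean_rsa=mean_rsa,
            mean_plddt=float(plddt[rows].mean()),
            exposed=mean_rsa >= rsa_threshold,
        ))
    return reports
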
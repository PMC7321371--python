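"""Cα-trace structures: PDB I/O, flattening, rigid superposition, RMSD.

The whole pipeline operates on Cα traces — one (x, y, z) position per
residue.  A trace of ``residue_count`` residues is flattened into a vector
of length ``3 * residue_count`` in atom-major order
``(x1, y1, z1, x2, y2, z2, ...)``; this is the single flattening convention
used by every matrix in the package.

Superposition is least-squares rigid-body (Kabsch); reflections are never
returned.  RMSD is the root-mean-square per-atom distance, optionally after
superposition.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "CaTrace",
    "SuperpositionResult",
    "DegenerateStructureError",
    "CorrespondenceError",
    "read_ca_trace",
    "write_ca_trace",
    "flatten",
    "unflatten",
    "superpose",
    "rmsd",
]


class DegenerateStructureError(ValueError):
    """Raised when a structure has too few Cα atoms to be usable (< 3)."""


class CorrespondenceError(ValueError):
    """Raised when two traces that must correspond residue-by-residue differ in length."""


@dataclass
class CaTrace:
    """An ordered Cα coordinate list for one structure.

    Parameters
    ----------
    coords : (residue_count, 3) float array
        Cα positions in Å, one row per residue, in chain order.
    label : str
        Free-text identifier (file stem, decoy name, ...).
    """

    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 3:
            raise DegenerateStructureError(
                f"a Cα trace needs at least 3 residues, got {self.coords.shape[0]}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")

    @property
    def residue_count(self) -> int:
        return self.coords.shape[0]

    def copy(self, label: str | None = None) -> "CaTrace":
        return CaTrace(self.coords.copy(), self.label if label is None else label)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class SuperpositionResult:
    """Optimal rigid-body transform of a mobile trace onto a reference.

    ``rotation`` is a proper rotation (det = +1); applying
    ``rotation @ x + translation`` to every mobile atom minimises the RMSD
    to the reference.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def read_ca_trace(path: str | os.PathLike, chain: str | None = None) -> CaTrace:
    """Read the Cα trace of a PDB file.

    Only ATOM/HETATM records are interpreted.  Alternate locations are
    resolved to the first occurrence per residue; residues without a Cα are
    skipped with a warning; insertion codes are ignored.

    Parameters
    ----------
    chain : str, optional
        Chain identifier to restrict to.  By default all chains are read in
        file order.
    """
    path = os.fspath(path)
    if not os.path.isfile(path):
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_pdb(path)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise IOError(f"cannot parse PDB file {path!r}: {exc}") from exc

    coords: list[list[float]] = []
    skipped = 0
    saw_icode = False
    if len(structure) == 0:
        raise DegenerateStructureError(f"{path!r}: no models")
    model = structure[0]
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for residue in ch:
            if residue.seqid.icode not in (" ", "", "\x00"):
                saw_icode = True
            ca = None
            for atom in residue:
                if atom.name == "CA" and atom.element.name in ("C", "X", ""):
                    ca = atom
                    break  # first occurrence wins for altlocs
            if ca is None:
                skipped += 1
                continue
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if skipped:
        warnings.warn(f"{path!r}: skipped {skipped} residue(s) lacking a Cα atom")
    if saw_icode:
        warnings.warn(f"{path!r}: insertion codes present and ignored")
    if len(coords) < 3:
        raise DegenerateStructureError(
            f"{path!r}: found {len(coords)} Cα atoms (need ≥ 3)"
        )
    label = os.path.splitext(os.path.basename(path))[0]
    return CaTrace(np.array(coords, dtype=float), label=label)


def write_ca_trace(trace: CaTrace, path: str | os.PathLike) -> None:
    """Write a trace as CA-only PDB ATOM records (residues numbered 1..n).

    Coordinates are written at the fixed 3-decimal PDB precision, so a
    write/read round trip reproduces them to 5e-4 Å.
    """
    path = os.fspath(path)
    if path == "" or os.path.isdir(path):
        raise IOError(f"invalid output path {path!r}")
    st = gemmi.Structure()
    st.name = trace.label or "trace"
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")
    for i, (x, y, z) in enumerate(trace.coords, start=1):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = 1.0
        atom.b_iso = 0.0
        res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(path)
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write PDB file {path!r}: {exc}") from exc


def flatten(trace: CaTrace) -> np.ndarray:
    """Flatten a trace to a length-``3n`` vector, atom-major: (x1,y1,z1,x2,...)."""
    return trace.coords.reshape(-1).copy()


def unflatten(vector: np.ndarray, label: str = "") -> CaTrace:
    """Inverse of :func:`flatten`."""
    vector = np.asarray(vector, dtype=float)
    if vector.ndim != 1 or vector.size % 3 != 0:
        raise ValueError(f"flattened vector length must be a multiple of 3, got {vector.shape}")
    return CaTrace(vector.reshape(-1, 3), label=label)


def superpose(mobile: CaTrace, reference: CaTrace) -> tuple[SuperpositionResult, CaTrace]:
    """Least-squares rigid superposition (Kabsch) of ``mobile`` onto ``reference``.

    Returns the optimal proper-rotation transform and the transformed mobile
    trace.  The residue correspondence is by index; lengths must match.
    Rank-deficient point sets (collinear/coincident) yield a deterministic
    optimal proper rotation via the SVD sign convention.
    """
    if mobile.residue_count != reference.residue_count:
        raise CorrespondenceError(
            f"residue counts differ: {mobile.residue_count} vs {reference.residue_count}"
        )
    mob_c = mobile.centroid()
    ref_c = reference.centroid()
    a = mobile.coords - mob_c
    b = reference.coords - ref_c
    with warnings.catch_warnings():
        # align_vectors warns for rank-deficient (e.g. collinear) point sets;
        # any optimal proper rotation is acceptable there.
        warnings.simplefilter("ignore", UserWarning)
        rot, rssd = Rotation.align_vectors(b, a)
    R = rot.as_matrix()
    translation = ref_c - R @ mob_c
    moved = (mobile.coords @ R.T) + translation
    value = float(np.sqrt(np.mean(np.sum((moved - reference.coords) ** 2, axis=1))))
    result = SuperpositionResult(rotation=R, translation=translation, rmsd=value)
    return result, CaTrace(moved, label=mobile.label)


def rmsd(a: CaTrace, b: CaTrace, superpose_first: bool = True) -> float:
    """Root-mean-square per-atom distance between two traces (Å).

    With ``superpose_first`` the minimum over all rigid transforms is
    returned (Kabsch); otherwise the traces are compared in place.
    """
    if a.residue_count != b.residue_count:
        raise CorrespondenceError(
            f"residue counts differ: {a.residue_count} vs {b.residue_count}"
        )
    if superpose_first:
        result, _ = superpose(a, b)
        return result.rmsd
    return float(np.sqrt(np.mean(np.sum((a.coords - b.coords) ** 2, axis=1))))
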
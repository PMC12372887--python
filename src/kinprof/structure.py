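"""Structural measurements on kinase-domain coordinates.

Parses PDB/mmCIF files (via gemmi) into a normalized model (hydrogens
dropped, one conformer per atom chosen by highest occupancy) and computes
the geometric quantities that define a kinase's conformational state:

* diagnostic atom-atom distances — D1 (alphaC-Glu+4 residue CA to DFG-Phe
  CZ), D2 (beta3-Lys CA to DFG-Phe CZ) and the beta3-Lys/alphaC-Glu
  CB-CB distance that probes the catalytic salt bridge;
* backbone Phi/Psi dihedrals (IUPAC convention) over the x-DFG-x window;
* disulfide detection by SG-SG distance;
* regulatory-spine continuity from minimum side-chain heavy-atom contacts;
* least-squares (Kabsch) rigid superposition.

All reported distances are in Angstrom and angles in degrees in the
half-open interval (-180, 180]; reporting rounds to one decimal, but every
computation keeps full precision.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "StructureModel",
    "KinaseAnchors",
    "DihedralRecord",
    "DisulfideBond",
    "SpineReport",
    "GeometryReport",
    "MissingAtomError",
    "StructureFormatError",
    "read_structure",
    "write_structure",
    "atom_distance",
    "dihedral_angle",
    "backbone_dihedrals",
    "detect_disulfides",
    "spine_contacts",
    "superpose",
    "apply_transform",
    "geometry_report",
    "AMPK_ALPHA2_ANCHORS",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
PEPTIDE_BOND_MAX = 2.5  # Angstrom; C-N longer than this is a chain break


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed or has no model."""


class MissingAtomError(KeyError):
    """Raised when a requested atom is absent after altloc resolution."""


@dataclass
class StructureModel:
    """A single model of a structure with normalized atoms."""

    structure_id: str
    structure: gemmi.Structure

    @property
    def model(self) -> gemmi.Model:
        return self.structure[0]

    def chain(self, chain_id: str) -> gemmi.Chain:
        for ch in self.model:
            if ch.name == chain_id:
                return ch
        raise KeyError(f"{self.structure_id}: no chain {chain_id!r}")

    def residue(self, chain_id: str, seqid: int, icode: str = " ") -> gemmi.Residue:
        for res in self.chain(chain_id):
            if res.seqid.num == seqid and (res.seqid.icode or " ") == (icode or " "):
                return res
        raise KeyError(f"{self.structure_id}: no residue {chain_id}/{seqid}{icode.strip()}")

    def has_residue(self, chain_id: str, seqid: int) -> bool:
        try:
            self.residue(chain_id, seqid)
            return True
        except KeyError:
            return False

    def atom_pos(self, chain_id: str, seqid: int, atom_name: str, icode: str = " ") -> np.ndarray:
        res = self.residue(chain_id, seqid, icode)
        for atom in res:
            if atom.name == atom_name:
                return np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        raise MissingAtomError(
            f"{self.structure_id}: residue {res.name} {chain_id}/{seqid} has no atom {atom_name!r}"
        )

    def protein_residue_numbers(self, chain_id: str) -> list[int]:
        """Author numbers of polymer (amino-acid) residues; heteroatoms excluded."""
        out = []
        for res in self.chain(chain_id):
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and info.is_amino_acid():
                out.append(res.seqid.num)
        return out

    def coordinates(self, chain_id: str, residues: Iterable[int], atom_name: str = "CA") -> np.ndarray:
        return np.array([self.atom_pos(chain_id, r, atom_name) for r in residues])


def _resolve_altlocs(structure: gemmi.Structure) -> None:
    """Keep one conformer per atom name: highest occupancy, ties to the
    alphabetically first altloc."""
    for model in structure:
        for chain in model:
            for res in chain:
                names: dict[str, list[int]] = {}
                for i, atom in enumerate(res):
                    names.setdefault(atom.name, []).append(i)
                drop: list[int] = []
                for idxs in names.values():
                    if len(idxs) > 1:
                        best = min(idxs, key=lambda i: (-res[i].occ, res[i].altloc or "A"))
                        drop.extend(i for i in idxs if i != best)
                for i in sorted(drop, reverse=True):
                    del res[i]
                for atom in res:
                    atom.altloc = "\0"


def read_structure(source: str | Path, model_index: int = 1) -> StructureModel:
    """Read a PDB or mmCIF file into a normalized :class:`StructureModel`.

    Hydrogens are removed, alternative conformations resolved to the
    highest-occupancy conformer, and only ``model_index`` (1-based) is kept.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: unreadable structure file: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: file contains no model")
    if not 1 <= model_index <= len(st):
        raise StructureFormatError(
            f"{path}: model {model_index} requested but file has {len(st)} model(s)"
        )
    keep = st[model_index - 1]
    while len(st) > 1:
        for i, m in enumerate(st):
            if m is not keep:
                del st[i]
                break
    st.remove_hydrogens()
    _resolve_altlocs(st)
    st.setup_entities()
    if sum(len(ch) for ch in st[0]) == 0:
        raise StructureFormatError(f"{path}: selected model is empty")
    return StructureModel(structure_id=st.name or path.stem, structure=st)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write as PDB or mmCIF depending on the file extension."""
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        model.structure.make_mmcif_document().write_file(str(path))
    else:
        model.structure.write_pdb(str(path))


# ---------------------------------------------------------------------------
# primitive measurements
# ---------------------------------------------------------------------------

def atom_distance(
    model: StructureModel,
    a: tuple[str, int, str],
    b: tuple[str, int, str],
) -> float:
    """Euclidean distance in Angstrom between two atoms given as
    (chain, residue number, atom name)."""
    pa = model.atom_pos(*a[:2], a[2])
    pb = model.atom_pos(*b[:2], b[2])
    return float(np.linalg.norm(pa - pb))


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0, dtype=float) - np.asarray(p1, dtype=float)
    b1 = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    b2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


@dataclass
class DihedralRecord:
    residue_number: int
    residue_name: str
    phi: float | None
    psi: float | None


def backbone_dihedrals(
    model: StructureModel,
    chain_id: str,
    residue_range: Sequence[int],
) -> list[DihedralRecord]:
    """Phi/Psi for each residue number in ``residue_range``.

    Phi(i) = torsion C(i-1), N(i), CA(i), C(i); Psi(i) = torsion N(i),
    CA(i), C(i), N(i+1).  An angle is reported as None at a chain terminus
    or across a peptide bond longer than 2.5 Angstrom (chain break, with a
    warning).
    """
    records = []
    for num in residue_range:
        res = model.residue(chain_id, num)
        phi = psi = None
        try:
            n = model.atom_pos(chain_id, num, "N")
            ca = model.atom_pos(chain_id, num, "CA")
            c = model.atom_pos(chain_id, num, "C")
        except (KeyError, MissingAtomError) as exc:
            raise MissingAtomError(
                f"residue {chain_id}/{num} lacks backbone atoms: {exc}"
            ) from exc
        try:
            c_prev = model.atom_pos(chain_id, num - 1, "C")
            if np.linalg.norm(n - c_prev) > PEPTIDE_BOND_MAX:
                warnings.warn(f"chain break before residue {chain_id}/{num}; phi undefined")
            else:
                phi = dihedral_angle(c_prev, n, ca, c)
        except KeyError:
            pass
        try:
            n_next = model.atom_pos(chain_id, num + 1, "N")
            if np.linalg.norm(n_next - c) > PEPTIDE_BOND_MAX:
                warnings.warn(f"chain break after residue {chain_id}/{num}; psi undefined")
            else:
                psi = dihedral_angle(n, ca, c, n_next)
        except KeyError:
            pass
        records.append(DihedralRecord(residue_number=num, residue_name=res.name, phi=phi, psi=psi))
    return records


@dataclass
class DisulfideBond:
    chain_a: str
    residue_a: int
    chain_b: str
    residue_b: int
    sg_distance: float


def detect_disulfides(model: StructureModel, max_sg_distance: float = 2.3) -> list[DisulfideBond]:
    """Cysteine pairs whose SG atoms lie within ``max_sg_distance``.

    Pairs are matched greedily nearest-first so each cysteine appears in at
    most one bond; the result is sorted by SG-SG distance.  Cysteines
    lacking an SG atom are skipped with a warning.
    """
    sgs: list[tuple[str, int, np.ndarray]] = []
    for chain in model.model:
        for res in chain:
            if res.name != "CYS":
                continue
            pos = None
            for atom in res:
                if atom.name == "SG":
                    pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    break
            if pos is None:
                warnings.warn(f"CYS {chain.name}/{res.seqid.num} has no SG atom; skipped")
                continue
            sgs.append((chain.name, res.seqid.num, pos))

    candidates = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][2] - sgs[j][2]))
            if d <= max_sg_distance:
                candidates.append((d, i, j))
    candidates.sort()
    used: set[int] = set()
    bonds = []
    for d, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        bonds.append(
            DisulfideBond(
                chain_a=sgs[i][0], residue_a=sgs[i][1],
                chain_b=sgs[j][0], residue_b=sgs[j][1],
                sg_distance=d,
            )
        )
    return bonds


@dataclass
class SpineReport:
    status: str  # "intact" | "broken"
    pair_distances: list[tuple[int, int, float | None]]
    breaking_pairs: list[tuple[int, int]]
    contact_cutoff: float


def _sidechain_coords(res: gemmi.Residue) -> np.ndarray:
    pts = [
        [a.pos.x, a.pos.y, a.pos.z]
        for a in res
        if a.name not in BACKBONE_ATOMS and a.element.name != "H"
    ]
    return np.array(pts) if pts else np.empty((0, 3))


def spine_contacts(
    model: StructureModel,
    spine_residues: Sequence[int],
    chain_id: str = "A",
    contact_cutoff: float = 4.5,
) -> SpineReport:
    """Regulatory-spine continuity from consecutive side-chain contacts.

    For each consecutive pair of spine residues the minimum distance over
    side-chain heavy atoms is computed; the spine is *broken* iff any pair
    exceeds ``contact_cutoff``.  A residue without side-chain heavy atoms
    breaks the spine at that link (warning).
    """
    if len(spine_residues) < 2:
        raise ValueError("need at least two spine residues")
    pair_distances: list[tuple[int, int, float | None]] = []
    breaking: list[tuple[int, int]] = []
    for a, b in zip(spine_residues, spine_residues[1:]):
        ca = _sidechain_coords(model.residue(chain_id, a))
        cb = _sidechain_coords(model.residue(chain_id, b))
        if len(ca) == 0 or len(cb) == 0:
            missing = a if len(ca) == 0 else b
            warnings.warn(f"spine residue {chain_id}/{missing} has no side-chain heavy atoms")
            pair_distances.append((a, b, None))
            breaking.append((a, b))
            continue
        d = float(np.min(np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)))
        pair_distances.append((a, b, d))
        if d > contact_cutoff:
            breaking.append((a, b))
    status = "broken" if breaking else "intact"
    return SpineReport(
        status=status,
        pair_distances=pair_distances,
        breaking_pairs=breaking,
        contact_cutoff=contact_cutoff,
    )


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    rotation: np.ndarray  # (3, 3), orthogonal, det +1
    translation: np.ndarray  # (3,)


def apply_transform(transform: RigidTransform, coords: np.ndarray) -> np.ndarray:
    return coords @ transform.rotation.T + transform.translation


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Kabsch least-squares rigid superposition of paired coordinates.

    Returns the proper rotation + translation mapping ``mobile`` onto
    ``target`` and the RMSD over the pairs after the transform.  Requires
    at least three non-collinear pairs.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atom pairs for superposition")
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    s = np.linalg.svd(mc, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) atom set; superposition undefined")
    h = mc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = target.mean(axis=0) - rot @ mobile.mean(axis=0)
    transform = RigidTransform(rotation=rot, translation=trans)
    moved = apply_transform(transform, mobile)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return transform, rmsd


# ---------------------------------------------------------------------------
# anchors and the composite report
# ---------------------------------------------------------------------------

@dataclass
class KinaseAnchors:
    """Role -> author residue number map for one kinase domain chain.

    Defaults are the AMPKalpha2 kinase domain: beta3 Lys45, alphaC Glu64,
    D1 anchor Leu68 (the alphaC-Glu+4 position), DFG triad 157-159 with
    the x-DFG-x window 156-160, gatekeeper Met93, HRD His137, a default
    regulatory-spine set (alphaC Leu68, DFG Phe158, HRD His137, alphaF
    Asp196) and the Cys106/Cys174 disulfide candidate pair.
    """

    chain_id: str = "A"
    beta3_lysine: int = 45
    alphaC_glutamate: int = 64
    d1_anchor: int = 68
    dfg_asp: int = 157
    dfg_phe: int = 158
    dfg_gly: int = 159
    xdfgx_span: tuple[int, ...] = (156, 157, 158, 159, 160)
    gatekeeper: int = 93
    hrd_histidine: int = 137
    spine_residues: tuple[int, ...] = (68, 158, 137, 196)
    disulfide_candidates: tuple[tuple[int, int], ...] = ((106, 174),)

    def __post_init__(self) -> None:
        if len(self.xdfgx_span) != 5:
            raise ValueError("xdfgx_span must list exactly five residues")

    def validate(self, model: StructureModel, roles: Sequence[str] | None = None) -> list[str]:
        """Return the anchor residues missing from the model.

        By default only the measurement-critical roles are checked (the
        residues every distance/dihedral needs); pass ``roles`` to also
        demand descriptive anchors such as the gatekeeper.
        """
        if roles is None:
            roles = (
                "beta3_lysine", "alphaC_glutamate", "d1_anchor",
                "dfg_asp", "dfg_phe", "dfg_gly",
            )
        missing = []
        for role in roles:
            num = getattr(self, role)
            if not model.has_residue(self.chain_id, num):
                missing.append(f"{role}={num}")
        return missing


AMPK_ALPHA2_ANCHORS = KinaseAnchors()


def _round1(x: float | None) -> float | None:
    return None if x is None else round(x, 1)


@dataclass
class GeometryReport:
    structure_id: str
    chain_id: str
    d1: float
    d2: float
    lys_glu_distance: float
    xdfgx_dihedrals: list[DihedralRecord]
    disulfides: list[DisulfideBond]
    spine: SpineReport | None

    def to_dict(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "chain_id": self.chain_id,
            "d1": _round1(self.d1),
            "d2": _round1(self.d2),
            "lys_glu_distance": _round1(self.lys_glu_distance),
            "xdfgx_dihedrals": [
                {
                    "residue_number": r.residue_number,
                    "residue_name": r.residue_name,
                    "phi": _round1(r.phi),
                    "psi": _round1(r.psi),
                }
                for r in self.xdfgx_dihedrals
            ],
            "disulfides": [asdict(b) | {"sg_distance": round(b.sg_distance, 2)} for b in self.disulfides],
            "spine": None
            if self.spine is None
            else {
                "status": self.spine.status,
                "contact_cutoff": self.spine.contact_cutoff,
                "pair_distances": [
                    [a, b, _round1(d)] for a, b, d in self.spine.pair_distances
                ],
                "breaking_pairs": [list(p) for p in self.spine.breaking_pairs],
            },
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def geometry_report(
    model: StructureModel,
    anchors: KinaseAnchors = AMPK_ALPHA2_ANCHORS,
    max_sg_distance: float = 2.3,
    spine_cutoff: float = 4.5,
    include_spine: bool = True,
) -> GeometryReport:
    """Compute all conformational measurements for one chain at once.

    D1 is the D1-anchor CA to DFG-Phe CZ distance, D2 the beta3-Lys CA to
    DFG-Phe CZ distance, and the Lys-Glu distance is CB-CB across the
    (possibly broken) catalytic salt bridge.
    """
    ch = anchors.chain_id
    d1 = atom_distance(model, (ch, anchors.d1_anchor, "CA"), (ch, anchors.dfg_phe, "CZ"))
    d2 = atom_distance(model, (ch, anchors.beta3_lysine, "CA"), (ch, anchors.dfg_phe, "CZ"))
    lys_glu = atom_distance(
        model, (ch, anchors.beta3_lysine, "CB"), (ch, anchors.alphaC_glutamate, "CB")
    )
    dihedrals = backbone_dihedrals(model, ch, anchors.xdfgx_span)
    disulfides = detect_disulfides(model, max_sg_distance=max_sg_distance)
    spine = None
    if include_spine:
        try:
            spine = spine_contacts(
                model, anchors.spine_residues, chain_id=ch, contact_cutoff=spine_cutoff
            )
        except KeyError as exc:
            warnings.warn(f"spine assessment skipped: {exc}")
    return GeometryReport(
        structure_id=model.structure_id,
        chain_id=ch,
        d1=d1,
        d2=d2,
        lys_glu_distance=lys_glu,
        xdfgx_dihedrals=dihedrals,
        disulfides=disulfides,
        spine=spine,
    )
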
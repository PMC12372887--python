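"""Synthetic fixtures with planted ground truth for every pipeline stage.

Every generator is a pure function of its arguments (seeded NumPy RNG, no
global state), and emits the planted truth alongside the data so that
downstream recovery tests are self-contained:

* panel tables with known inhibited / non-inhibited / in-between labels;
* MSAs with planted per-column conservation (single-residue "conserved"
  columns vs uniformly sampled "variable" columns, optional gap columns);
* toy 3-D structures built by sequential internal-coordinate placement
  (ideal bond lengths/angles, torsions set to targets), with optional
  planted disulfide SG-SG distances, planted D1/D2/Lys-Glu anchor
  distances and planted regulatory-spine spacings;
* noisy concentration-response curves from the binding models.

The toy structures are geometric fixtures, not physically realistic
proteins: side chains exist only where a measurement needs them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import BindingCurve, dilution_series, dose_response_predict, total_binding_predict
from .panel import PanelRecord
from .structure import StructureModel

__all__ = [
    "SyntheticSpec",
    "ConstraintError",
    "make_panel",
    "make_msa",
    "make_structure",
    "make_curve",
    "build_backbone",
    "reference_standin_structure",
    "load_reference_geometry",
    "generate",
]

# ideal backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 117.0
ANGLE_C_N_CA = 121.0
OMEGA_TRANS = 180.0

DFG_NAMES = {156: "ALA", 157: "ASP", 158: "PHE", 159: "GLY", 160: "LEU"}


class ConstraintError(ValueError):
    """Raised when planted geometric constraints are infeasible."""


@dataclass
class SyntheticSpec:
    """Declarative description of one synthetic dataset (CLI entry point)."""

    seed: int
    kind: str  # panel | msa | structure | curve
    parameters: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry: internal-coordinate placement
# ---------------------------------------------------------------------------

def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, chi: float
) -> np.ndarray:
    """Position atom D so that |CD| = r, angle(B,C,D) = theta and the
    torsion A-B-C-D equals chi (degrees)."""
    theta = math.radians(theta)
    chi = math.radians(chi)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = r * (-math.cos(theta) * bc + math.sin(theta) * (math.cos(chi) * m + math.sin(chi) * n))
    return c + d


def build_backbone(
    residue_numbers: Sequence[int],
    torsions: Mapping[int, tuple[float | None, float | None]],
    default_phi: float = -60.0,
    default_psi: float = -45.0,
) -> dict[int, dict[str, np.ndarray]]:
    """N/CA/C coordinates for a contiguous run of residues with target
    Phi/Psi torsions (omega fixed trans).

    ``torsions[num] = (phi, psi)``; None (or absent) falls back to the
    defaults.  Phi of the first residue and Psi of the last are not
    realizable (no flanking peptide) and are ignored.
    """
    nums = list(residue_numbers)
    if nums != list(range(nums[0], nums[0] + len(nums))):
        raise ValueError("residue_numbers must be contiguous ascending")

    def tor(num: int, idx: int) -> float:
        pair = torsions.get(num, (None, None))
        val = pair[idx] if pair[idx] is not None else (default_phi, default_psi)[idx]
        if not (-180.0 < val <= 180.0):
            raise ConstraintError(f"torsion {val} for residue {num} outside (-180, 180]")
        return float(val)

    coords: dict[int, dict[str, np.ndarray]] = {}
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords[nums[0]] = {"N": n0, "CA": ca0, "C": c0}
    for prev, num in zip(nums, nums[1:]):
        p = coords[prev]
        n_next = place_atom(p["N"], p["CA"], p["C"], BOND_C_N, ANGLE_CA_C_N, tor(prev, 1))
        ca_next = place_atom(p["CA"], p["C"], n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        c_next = place_atom(p["C"], n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, tor(num, 0))
        coords[num] = {"N": n_next, "CA": ca_next, "C": c_next}
    return coords


def _new_structure(structure_id: str, chain_id: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure_id
    model = gemmi.Model("1")
    model.add_chain(gemmi.Chain(chain_id))
    st.add_model(model)
    return st


def _add_atom(res: gemmi.Residue, name: str, element: str, pos: np.ndarray) -> None:
    atom = gemmi.Atom()
    atom.name = name
    atom.element = gemmi.Element(element)
    atom.pos = gemmi.Position(*map(float, pos))
    atom.occ = 1.0
    res.add_atom(atom)


def make_structure(
    seed: int,
    *,
    structure_id: str = "synthetic",
    chain_id: str = "A",
    first_residue: int = 154,
    n_residues: int = 9,
    torsions: Mapping[int, tuple[float | None, float | None]] | None = None,
    disulfide: tuple[int, int, float] | None = None,
    anchor_distances: Mapping[str, float] | None = None,
    spine: tuple[Sequence[int], Sequence[float]] | None = None,
    out_path: str | Path | None = None,
) -> tuple[StructureModel, dict]:
    """Toy structure with exactly planted geometry.

    * ``torsions`` plants backbone Phi/Psi on the contiguous run
      ``first_residue .. first_residue + n_residues - 1``;
    * ``disulfide = (res_a, res_b, sg_distance)`` plants two cysteines with
      that SG-SG distance;
    * ``anchor_distances = {"d1":, "d2":, "lys_glu":}`` plants atoms for
      residues Lys45 (CA, CB), Glu64 (CB), Leu68 (CA) and a Phe158 CZ so
      the three diagnostic distances are realized exactly;
    * ``spine = (residues, gaps)`` plants one CB per listed residue with
      the stated consecutive CB-CB spacings.

    Returns the model plus a dict of the planted truth.  Everything is a
    pure function of the arguments; the seed is carried into the truth
    record for provenance only (no randomness is involved).
    """
    torsions = {int(k): tuple(v) for k, v in (torsions or {}).items()}
    residue_numbers = list(range(first_residue, first_residue + n_residues))
    backbone = build_backbone(residue_numbers, torsions)

    residues: dict[int, tuple[str, list[tuple[str, str, np.ndarray]]]] = {}

    def ensure(num: int, name: str) -> list:
        if num not in residues:
            residues[num] = (name, [])
        return residues[num][1]

    for num in residue_numbers:
        name = DFG_NAMES.get(num, "ALA")
        atoms = ensure(num, name)
        for an in ("N", "CA", "C"):
            atoms.append((an, an[0], backbone[num][an]))

    truth: dict = {"seed": seed, "torsions": {}, "chain_id": chain_id}
    for num in residue_numbers:
        phi, psi = torsions.get(num, (None, None))
        realizable_phi = phi if num > residue_numbers[0] else None
        realizable_psi = psi if num < residue_numbers[-1] else None
        if realizable_phi is not None or realizable_psi is not None:
            truth["torsions"][num] = (realizable_phi, realizable_psi)

    if disulfide is not None:
        res_a, res_b, sg_dist = disulfide
        if sg_dist <= 0:
            raise ConstraintError(f"planted SG-SG distance must be > 0, got {sg_dist}")
        base = np.array([-50.0, -50.0, -50.0])
        for num, sg in ((res_a, base), (res_b, base + np.array([sg_dist, 0.0, 0.0]))):
            atoms = ensure(num, "CYS")
            atoms.append(("CA", "C", sg + np.array([0.0, 0.0, 1.8])))
            atoms.append(("SG", "S", sg))
        truth["disulfide"] = {"residues": (res_a, res_b), "sg_distance": sg_dist}

    if anchor_distances is not None:
        d1 = float(anchor_distances["d1"])
        d2 = float(anchor_distances["d2"])
        lys_glu = float(anchor_distances["lys_glu"])
        if min(d1, d2, lys_glu) <= 0:
            raise ConstraintError("anchor distances must all be > 0")
        off = np.array([100.0, 100.0, 100.0])
        cz = off
        leu68_ca = off + np.array([d1, 0.0, 0.0])
        lys45_ca = off + d2 * np.array([math.cos(math.radians(60)), math.sin(math.radians(60)), 0.0])
        lys45_cb = lys45_ca + np.array([0.0, 0.0, 1.53])
        glu64_cb = lys45_cb + np.array([0.0, lys_glu, 0.0])
        ensure(45, "LYS").extend([("CA", "C", lys45_ca), ("CB", "C", lys45_cb)])
        ensure(64, "GLU").append(("CB", "C", glu64_cb))
        ensure(68, "LEU").append(("CA", "C", leu68_ca))
        atoms158 = ensure(158, "PHE")
        atoms158.append(("CZ", "C", cz))
        truth["anchor_distances"] = {"d1": d1, "d2": d2, "lys_glu": lys_glu}

    if spine is not None:
        spine_res, gaps = spine
        if len(gaps) != len(spine_res) - 1:
            raise ConstraintError("need one gap per consecutive spine pair")
        if any(g <= 0 for g in gaps):
            raise ConstraintError("spine gaps must be > 0")
        pos = np.array([-100.0, -100.0, -100.0])
        cum = 0.0
        for i, num in enumerate(spine_res):
            atoms = ensure(num, residues.get(num, ("ALA",))[0])
            atoms.append(("CB", "C", pos + np.array([cum, 0.0, 0.0])))
            if i < len(gaps):
                cum += float(gaps[i])
        truth["spine"] = {"residues": list(spine_res), "gaps": list(map(float, gaps))}

    st = _new_structure(structure_id, chain_id)
    chain = st[0][0]
    for num in sorted(residues):
        name, atoms = residues[num]
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(num, " ")
        for atom_name, element, pos in atoms:
            _add_atom(res, atom_name, element, pos)
        chain.add_residue(res)
    st.setup_entities()
    model = StructureModel(structure_id=structure_id, structure=st)
    if out_path is not None:
        model.structure.write_pdb(str(out_path))
    return model, truth


def load_reference_geometry() -> dict:
    """Packaged published distance/dihedral measurements for the AMPKalpha2
    inhibitor co-structures (used as classification inputs and as targets
    for synthetic stand-ins)."""
    from importlib import resources

    return json.loads(
        resources.files("kinprof.data").joinpath("reference_geometry.json").read_text()
    )


def reference_standin_structure(
    name: str, seed: int = 0, out_path: str | Path | None = None
) -> tuple[StructureModel, dict]:
    """Synthetic stand-in for a published co-structure.

    Builds a toy model whose x-DFG-x torsions and D1/D2/Lys-Glu distances
    are planted at the published values for ``name`` (a key of the
    packaged reference table).  This is *not* the crystallographic
    coordinate set — it is a geometric replica of the published
    measurements for exercising the measurement code.
    """
    ref = load_reference_geometry()["structures"]
    if name not in ref:
        raise KeyError(f"unknown reference structure {name!r}; options: {sorted(ref)}")
    entry = ref[name]
    torsions = {int(num): (phi, psi) for num, (phi, psi) in entry["xdfgx"].items()}
    model, truth = make_structure(
        seed,
        structure_id=f"standin-{name}",
        first_residue=155,
        n_residues=7,
        torsions=torsions,
        anchor_distances={"d1": entry["d1"], "d2": entry["d2"], "lys_glu": entry["lys_glu"]},
        out_path=out_path,
    )
    truth["reference"] = name
    return model, truth


# ---------------------------------------------------------------------------
# panel / MSA / curve generators
# ---------------------------------------------------------------------------

def make_panel(
    seed: int,
    n_inhibited: int = 7,
    n_noninhibited: int = 10,
    n_between: int = 123,
    compound_id: str = "CMPD-A",
    inhibited_cutoff: float = 50.0,
    noninhibited_cutoff: float = 99.0,
) -> tuple[list[PanelRecord], dict[str, str]]:
    """Panel table with a planted three-way partition.

    Defaults emulate a 140-kinase selectivity panel with a small inhibited
    group and a small representative non-inhibited group.  Activities are
    drawn so every planted label is recoverable exactly from the cutoffs.
    """
    rng = np.random.default_rng(seed)
    n_total = n_inhibited + n_noninhibited + n_between
    ids = [f"K{i + 1:03d}" for i in range(n_total)]
    labels = (
        ["inhibited"] * n_inhibited
        + ["noninhibited"] * n_noninhibited
        + ["unclassified"] * n_between
    )
    perm = rng.permutation(n_total)
    records, truth = [], {}
    for idx in perm:
        kid, label = ids[idx], labels[idx]
        if label == "inhibited":
            activity = rng.uniform(0.0, inhibited_cutoff)
        elif label == "noninhibited":
            activity = rng.uniform(noninhibited_cutoff, 110.0)
        else:
            lo = np.nextafter(inhibited_cutoff, np.inf)
            hi = np.nextafter(noninhibited_cutoff, -np.inf)
            activity = rng.uniform(lo, hi)
        records.append(
            PanelRecord(
                kinase_id=kid,
                compound_id=compound_id,
                remaining_activity=float(activity),
                sem=float(rng.uniform(0.1, 3.0)),
                n_replicates=2,
            )
        )
        truth[kid] = label
    return records, truth


def make_msa(
    seed: int,
    n_seqs: int = 50,
    column_kinds: Sequence[str] | None = None,
    n_conserved: int = 20,
    n_variable: int = 20,
    n_intermediate: int = 50,
    n_gap: int = 0,
    variable_alphabet: str = "ACDEFGHIKL",
    intermediate_majority: float = 0.7,
    reference_id: str = "REF",
) -> tuple[MultipleSeqAlignment, list[str]]:
    """Alignment with planted per-column conservation labels.

    ``column_kinds`` lists "conserved" / "variable" / "intermediate" /
    "gap" per column; when omitted, ``n_conserved`` conserved columns are
    followed by ``n_variable`` variable, ``n_intermediate`` intermediate
    and ``n_gap`` fully gapped columns.  Conserved columns carry a single
    residue; variable columns sample uniformly from ``variable_alphabet``;
    intermediate columns hold a majority residue at fraction
    ``intermediate_majority`` with the remainder sampled from the variable
    alphabet — real kinase-domain alignments are dominated by such
    mid-conservation columns, with fully conserved and fully variable
    positions in the minority.  The first sequence (the reference) is kept
    non-gap on every non-gap column so reference mapping is total.
    """
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    rng = np.random.default_rng(seed)
    if column_kinds is None:
        column_kinds = (
            ["conserved"] * n_conserved
            + ["variable"] * n_variable
            + ["intermediate"] * n_intermediate
            + ["gap"] * n_gap
        )
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    var_alpha = np.array(list(variable_alphabet))
    cols = []
    for kind in column_kinds:
        if kind == "conserved":
            cols.append(np.full(n_seqs, rng.choice(alphabet)))
        elif kind == "variable":
            cols.append(rng.choice(var_alpha, size=n_seqs))
        elif kind == "intermediate":
            majority = rng.choice(alphabet)
            col = rng.choice(var_alpha, size=n_seqs)
            keep = rng.random(n_seqs) < intermediate_majority
            col[keep] = majority
            cols.append(col)
        elif kind == "gap":
            cols.append(np.full(n_seqs, "-"))
        else:
            raise ValueError(f"unknown column kind {kind!r}")
    mat = np.column_stack(cols) if cols else np.empty((n_seqs, 0), dtype="<U1")
    records = []
    for i in range(n_seqs):
        sid = reference_id if i == 0 else f"SEQ{i:03d}"
        records.append(SeqRecord(Seq("".join(mat[i])), id=sid, description=""))
    return MultipleSeqAlignment(records), list(column_kinds)


def make_curve(
    seed: int,
    model: str = "total_binding",
    params: Mapping[str, float] | None = None,
    noise_sigma: float = 0.0,
    top_concentration: float = 250.0,
    factor: float = 2.0,
    n_points: int = 16,
    replicates: int = 2,
) -> tuple[BindingCurve, dict[str, float]]:
    """Noisy concentration-response curve from a stated model.

    X follows the serial-dilution design (default 1:1 over 16 steps from
    250 uM, two technical replicates per concentration); Y is the model
    prediction plus seeded Gaussian noise of standard deviation
    ``noise_sigma`` (same units as Y).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.tile(dilution_series(top_concentration, factor, n_points), replicates)
    if model == "total_binding":
        p = dict(params or {"bmax": 100.0, "kd": 2.0, "ns": 0.05, "background": 5.0})
        y = total_binding_predict(x, p["bmax"], p["kd"], p["ns"], p["background"])
    elif model == "dose_response":
        p = dict(params or {"top": 100.0, "bottom": 0.0, "ic50": 0.5, "hill_slope": -1.0})
        y = dose_response_predict(x, p["top"], p["bottom"], p["ic50"], p["hill_slope"])
    else:
        raise ValueError(f"unknown model {model!r}")
    y = np.asarray(y, dtype=float) + rng.normal(0.0, noise_sigma, size=x.shape)
    reps = np.repeat(np.arange(1, replicates + 1), n_points)
    return BindingCurve(x=x, y=y, replicate_ids=reps), p


# ---------------------------------------------------------------------------
# CLI-facing dispatch
# ---------------------------------------------------------------------------

def generate(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, str]:
    """Materialize a synthetic dataset to disk; returns written file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    if spec.kind == "panel":
        from .panel import write_panel_table

        records, truth = make_panel(spec.seed, **spec.parameters)
        data_path = out_dir / "panel.csv"
        write_panel_table(records, data_path)
        truth_path = out_dir / "panel_truth.json"
        truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
        written = {"data": str(data_path), "truth": str(truth_path)}
    elif spec.kind == "msa":
        from .conservation import write_msa

        aln, labels = make_msa(spec.seed, **spec.parameters)
        data_path = out_dir / "msa.fasta"
        write_msa(aln, data_path)
        truth_path = out_dir / "msa_truth.json"
        truth_path.write_text(json.dumps({"column_kinds": labels}, indent=2) + "\n")
        written = {"data": str(data_path), "truth": str(truth_path)}
    elif spec.kind == "structure":
        data_path = out_dir / "structure.pdb"
        _, truth = make_structure(spec.seed, out_path=data_path, **spec.parameters)
        truth_path = out_dir / "structure_truth.json"
        truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True, default=list) + "\n")
        written = {"data": str(data_path), "truth": str(truth_path)}
    elif spec.kind == "curve":
        curve, params = make_curve(spec.seed, **spec.parameters)
        data_path = out_dir / "curve.csv"
        import pandas as pd

        pd.DataFrame(
            {"concentration": curve.x, "response": curve.y, "replicate": curve.replicate_ids}
        ).to_csv(data_path, index=False)
        truth_path = out_dir / "curve_truth.json"
        truth_path.write_text(json.dumps(params, indent=2, sort_keys=True) + "\n")
        written = {"data": str(data_path), "truth": str(truth_path)}
    else:
        raise ValueError(f"unknown synthetic kind {spec.kind!r}")
    return written
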
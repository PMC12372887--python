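import numpy as np
import pytest

from kinprof.synth import make_msa, make_panel, make_structure


@pytest.fixture
def panel_140():
    """Synthetic 140-kinase panel with planted group labels."""
    records, truth = make_panel(seed=11)
    return records, truth


@pytest.fixture
def planted_msa():
    """50-sequence MSA: 20 planted-conserved and 20 planted-variable
    columns on a background of 50 intermediate-conservation columns."""
    return make_msa(seed=7, n_seqs=50, n_conserved=20, n_variable=20, n_intermediate=50)


@pytest.fixture
def dfg_backbone():
    """Toy backbone (residues 154-162) with planted x-DFG-x torsions."""
    torsions = {
        156: (-77.8, 133.2),
        157: (-64.3, 162.0),
        158: (-90.6, 42.6),
        159: (-91.5, 174.0),
        160: (-69.5, -13.6),
    }
    model, truth = make_structure(seed=0, first_residue=154, n_residues=9, torsions=torsions)
    return model, torsions


def random_rigid_motion(rng):
    """A uniformly random proper rotation plus a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    trans = rng.normal(scale=20.0, size=3)
    return rot, trans


def transform_model(model, rot, trans):
    """Apply a rigid motion to every atom of a StructureModel in place."""
    import gemmi

    for chain in model.model:
        for res in chain:
            for atom in res:
                p = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                p = rot @ p + trans
                atom.pos = gemmi.Position(*p)
    return model
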
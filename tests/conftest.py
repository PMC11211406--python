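import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", module="MDAnalysis")

from pbcpack.components import Component  # noqa: E402

WATER_PDB = """\
ATOM      1  OH2 HOH A   1       0.000   0.000   0.000  1.00  0.00      WAT  O
ATOM      2  H1  HOH A   1       0.957   0.000   0.000  1.00  0.00      WAT  H
ATOM      3  H2  HOH A   1      -0.240   0.927   0.000  1.00  0.00      WAT  H
END
"""

# three alanine-like residues, no segid column -> chain fallback
PROTEIN_PDB_NO_SEGID = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      7  N   LYS A   3       5.332   2.736   0.500  1.00  0.00           N
ATOM      8  CA  LYS A   3       6.088   3.939   0.800  1.00  0.00           C
END
"""


@pytest.fixture
def water_pdb(tmp_path):
    p = tmp_path / "water.pdb"
    p.write_text(WATER_PDB)
    return p


@pytest.fixture
def protein_pdb(tmp_path):
    p = tmp_path / "protein.pdb"
    p.write_text(PROTEIN_PDB_NO_SEGID)
    return p


def make_component(positions, elements=None, seg_ids=None, res_names=None,
                   res_indices=None, comp_type="solvated", names=None):
    positions = np.asarray(positions, float).reshape(-1, 3)
    n = len(positions)
    elements = np.array(elements if elements is not None else ["C"] * n)
    return Component(
        names=np.array(names if names is not None else [f"A{i}" for i in range(n)]),
        elements=elements,
        positions=positions,
        res_names=np.array(res_names if res_names is not None else ["UNK"] * n),
        res_indices=np.array(res_indices if res_indices is not None else [1] * n, int),
        seg_ids=np.array(seg_ids if seg_ids is not None else ["MAIN"] * n),
        comp_type=comp_type,
    )


@pytest.fixture
def co2_component():
    return make_component(
        [[0.0, 0, 0], [1.16, 0, 0], [-1.16, 0, 0]],
        elements=["C", "O", "O"],
        res_names=["CO2"] * 3,
        seg_ids=["CO2"] * 3,
        comp_type="solvent",
        names=["C", "O1", "O2"],
    )


@pytest.fixture(scope="session")
def easy_bodies():
    """Three near-spherical rigid bodies with metrics precomputed."""
    from pbcpack.geometry import ensure_metrics
    from pbcpack.synthetic import easy_set

    bodies = easy_set(seed=0)
    for b in bodies:
        ensure_metrics(b)
    return bodies


@pytest.fixture(scope="session")
def membrane_body():
    """A synthetic membrane-embedded body spanning the 24 Å slab."""
    from pbcpack.geometry import ensure_metrics, principal_frame
    from pbcpack.synthetic import generate_blob

    b = generate_blob(150, 0.3, seed=5)
    pos = b.positions @ principal_frame(b.positions, b.masses).T
    pos = pos[:, [1, 2, 0]]  # long axis onto Z
    pos[:, 2] *= 2.0
    out = b.with_positions(pos - pos.mean(axis=0))
    out.comp_type = "membrane_embedded"
    ensure_metrics(out)
    return out
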
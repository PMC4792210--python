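import warnings

import numpy as np
import pytest
from hypothesis import settings

from distscore.bundle_model import BundleDefinition, HelixSegment
from distscore.structure_io import ChainBundle

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_bundle(helix_lengths, family="toy"):
    """Tiny bundle definition for tests; silences the short-helix warning."""
    helices = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for k, n in enumerate(helix_lengths):
            start = 50 - n // 2
            helices.append(HelixSegment("ABCDEFG"[k], start, start + n - 1))
    return BundleDefinition(family_name=family, helices=tuple(helices))


def make_chain(coords, bundle, present=None, structure_id="toy", chain_id="A"):
    coords = np.asarray(coords, dtype=float)
    if present is None:
        present = np.ones(len(coords), dtype=bool)
    return ChainBundle(structure_id, chain_id, coords, present, bundle)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


@pytest.fixture(scope="session")
def mr_bundle():
    from distscore import mr_reference_bundle

    return mr_reference_bundle()


@pytest.fixture(scope="session")
def br_mapping():
    from distscore import br_reference_mapping

    return br_reference_mapping()


# Minimal hand-written PDB fixture: chain A with three residues at known
# coordinates, one altloc'd Cα pair on residue 12, plus a chain B residue.
def pdb_atom(serial, name, alt, resname, chain, num, x, y, z, occ=1.0, element=" C"):
    return (
        f"ATOM  {serial:5d} {name:<4s}{alt}{resname:>3s} {chain}{num:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture
def tiny_pdb(tmp_path):
    lines = [
        pdb_atom(1, " N", " ", "ALA", "A", 11, 0.0, 0.0, -1.0, element=" N"),
        pdb_atom(2, " CA", " ", "ALA", "A", 11, 1.0, 2.0, 3.0),
        pdb_atom(3, " CA", "A", "GLY", "A", 12, 4.0, 5.0, 6.0, occ=0.5),
        pdb_atom(4, " CA", "B", "GLY", "A", 12, 7.0, 8.0, 9.0, occ=0.5),
        pdb_atom(5, " CA", " ", "SER", "A", 13, -1.0, -2.0, -3.0),
        pdb_atom(6, " CA", " ", "LEU", "B", 11, 9.0, 9.0, 9.0),
        "END",
    ]
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
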
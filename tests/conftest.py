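import pytest
from hypothesis import settings

from ppiface.synthetic_fixtures import make_burial_dimer, make_interaction_geometry, write_pdb

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

ALL_REGION_LABELS = ["core", "support", "rim_interacting", "rim_nis", "interior", "surface"]


@pytest.fixture(scope="session")
def burial_dimer():
    """Two-chain dimer with one probe residue per region label, verified at
    build time against the package's own SASA."""
    return make_burial_dimer(ALL_REGION_LABELS, n_points=960)


@pytest.fixture(scope="session")
def salt_bridge_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("fixtures") / "salt_bridge.pdb"
    write_pdb(make_interaction_geometry("salt_bridge", True), path)
    return path


@pytest.fixture(scope="session")
def hbond_salt_dimer_pdb(tmp_path_factory):
    """A dimer holding one ideal salt bridge and one ideal hydrogen bond,
    as two well-separated residue pairs."""
    import numpy as np
    from ppiface.structure_io import StructureModel

    sb = make_interaction_geometry("salt_bridge", True)
    hb = make_interaction_geometry("hbond", True)
    chains = {"A": [], "B": []}
    seq = 1
    for model, shift in ((sb, np.zeros(3)), (hb, np.array([60.0, 0.0, 0.0]))):
        for cid in ("A", "B"):
            for res in model.chains[cid]:
                res.seq_number = seq
                for a in res.atoms:
                    a.coords = a.coords + shift
                chains[cid].append(res)
                seq += 1
    combined = StructureModel("two_pairs", chains, {"format": "synthetic"})
    path = tmp_path_factory.mktemp("fixtures2") / "two_pairs.pdb"
    write_pdb(combined, path)
    return path
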
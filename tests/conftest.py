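import numpy as np
import pytest

import translodyn as td


@pytest.fixture(scope="session")
def mini():
    """Mini-ribosome structure with resolved groups."""
    structure, gspecs = td.make_mini_ribosome()
    groups = td.resolve_groups(structure, gspecs)
    return structure, gspecs, groups


@pytest.fixture(scope="session")
def refaxes(mini):
    """Reference axes built from the synthetic endpoint pair."""
    structure, _, groups = mini
    classical, rotated = td.make_reference_pair(structure)
    axes = td.define_reference_axes(classical, rotated, groups["mrna"],
                                    groups["body"], groups["head"],
                                    groups["large"])
    return classical, rotated, axes


def make_chain(n=10, seed=3, curl=0.3):
    """A mildly curved bead chain, one residue per atom."""
    rng = np.random.default_rng(seed)
    coords = np.cumsum(rng.normal(0, 1, (n, 3)) * curl
                       + np.array([1.4, 0.2, 0.1]), axis=0)
    return td.Structure(
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        res_ids=np.arange(1, n + 1),
        res_names=np.array(["GLY"] * n, dtype=object),
        chain_ids=np.array(["A"] * n, dtype=object),
        coords=coords)


@pytest.fixture(scope="session")
def toy_chain():
    structure = make_chain()
    topo = td.build_single_basin(
        structure, td.ForcefieldParams(min_seq_sep=2, cutoff=6.0))
    return structure, topo
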
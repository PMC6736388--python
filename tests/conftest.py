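"""Shared fixtures: synthetic families and derived ensembles.

Heavy objects (the default family, its refined ensemble, its matched GNM
mode ensemble) are session-scoped so the whole suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import famdyn as fd


@pytest.fixture(scope="session")
def default_family():
    return fd.generate_family(fd.FamilySpec())


@pytest.fixture(scope="session")
def family_dir(default_family, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("family")
    paths = fd.write_family(default_family, outdir)
    return paths


@pytest.fixture(scope="session")
def ensemble(family_dir):
    structures = fd.load_structures(family_dir["pdb"])
    msa = fd.read_msa(family_dir["msa"])
    labels = fd.read_labels(family_dir["labels"])
    ens = fd.build_ensemble(structures, msa, labels=labels)
    return fd.refine(ens)


@pytest.fixture(scope="session")
def gnm_ensemble(ensemble):
    return fd.build_mode_ensemble(ensemble, fd.ModelKind.GNM)


@pytest.fixture(scope="session")
def anm_ensemble(ensemble):
    return fd.build_mode_ensemble(ensemble, fd.ModelKind.ANM, n_modes=30)


@pytest.fixture(scope="session")
def base_modes():
    base = fd.generate_base_fold()
    return fd.decompose(fd.build_kirchhoff(base.ca_coords), member_id="base")


def random_connected_coords(rng, n=12, spread=6.0):
    """Random 3-D beads, rejected until the 10 Å GNM is connected."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    while True:
        pts = rng.uniform(0, spread, size=(n, 3))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        off = ~np.eye(n, dtype=bool)
        if d[off].min() < 1.0:
            continue
        adj = csr_matrix((d <= 10.0) & off)
        if connected_components(adj, directed=False)[0] == 1:
            return pts
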
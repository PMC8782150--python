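import numpy as np
import pytest

from emitissue.geometry import (CellCollectionSpec, EMIParameters,
                                build_box_collection, build_cell_collection,
                                compute_metrics)

ALL_DIRICHLET = {"x": "dirichlet", "y": "dirichlet", "z": "dirichlet"}


@pytest.fixture(scope="session")
def params():
    return EMIParameters()


@pytest.fixture(scope="session")
def box_fixture_mesh():
    """Two abutting 100x10x10 um box cells, 2 um padding, 1 um voxels."""
    return build_box_collection((2, 1, 1), cell_size=(100.0, 10.0, 10.0),
                                padding=2.0, voxel_size=1.0)


@pytest.fixture(scope="session")
def box_fixture_metrics(box_fixture_mesh):
    return compute_metrics(box_fixture_mesh)


@pytest.fixture(scope="session")
def small_strand_mesh():
    """Two tapered cells of 40 um at 2 um voxels (fast solver fixture)."""
    return build_cell_collection(CellCollectionSpec(
        n_cells=(2, 1, 1), cell_length=40.0, voxel_size=2.0))


@pytest.fixture(scope="session")
def tiny_box_mesh():
    """Two short box cells, <1000 unknowns, for dense-oracle checks."""
    return build_box_collection((2, 1, 1), cell_size=(20.0, 8.0, 8.0),
                                padding=2.0, voxel_size=2.0)
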
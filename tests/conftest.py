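import numpy as np
import pytest

from sonoplan.beams import compute_dose_matrix, sample_candidate_beams
from sonoplan.study import desk_constraints, desk_phantom


@pytest.fixture(scope="session")
def desk_case():
    """One compact pelvic phantom shared across the suite."""
    ct, structures, grid = desk_phantom(11)
    return ct, structures, grid


@pytest.fixture(scope="session")
def desk_beams(desk_case):
    _, _, grid = desk_case
    return sample_candidate_beams(grid, 500, seed=21)


@pytest.fixture(scope="session")
def desk_dose(desk_case, desk_beams):
    ct, structures, grid = desk_case
    return compute_dose_matrix(ct, grid, desk_beams, structures=structures)


@pytest.fixture(scope="session")
def constraints():
    return desk_constraints()


def random_lp_instance(rng, n_beams=5, n_ptv=10, n_oar=6, n_shell=8):
    """Tiny synthetic dose matrix with PTV/OAR/shell row blocks."""
    from scipy import sparse

    from sonoplan.beams import DoseMatrix

    rows = []
    for n in (n_ptv, n_oar, n_shell):
        block = rng.uniform(0.0, 0.4, size=(n, n_beams))
        block[rng.random(block.shape) < 0.3] = 0.0
        rows.append(block)
    mat = np.vstack(rows)
    slices = {
        "PTV": slice(0, n_ptv),
        "BLADDER": slice(n_ptv, n_ptv + n_oar),
        "RECTUM": slice(n_ptv + n_oar, n_ptv + n_oar),
        "SHELL3": slice(n_ptv + n_oar, n_ptv + n_oar + n_shell),
        "SHELL9": slice(n_ptv + n_oar + n_shell, n_ptv + n_oar + n_shell),
    }
    points = rng.normal(size=(mat.shape[0], 3))
    return DoseMatrix(sparse.csr_matrix(mat), slices, points, d0=1.0)
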
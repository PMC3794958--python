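import warnings

import numpy as np
import pytest
import trimesh

from subshape.mesh_core import TriangleMesh, compute_harmonics
from subshape.synthetic_data import CohortSpec, compute_bases, make_templates

# anisotropic templates legitimately contain obtuse triangles; the
# conditioning warning is itself under test in test_mesh_core
warnings.filterwarnings(
    "ignore", message=".*obtuse triangles.*", category=RuntimeWarning
)


def icosphere_mesh(subdivisions: int = 3, scale=(1.0, 1.0, 1.0),
                   tag: str = "other") -> TriangleMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions)
    return TriangleMesh(
        np.asarray(ico.vertices) * np.asarray(scale, float),
        np.asarray(ico.faces),
        tag,
    )


@pytest.fixture(scope="session")
def unit_sphere():
    return icosphere_mesh(3)


@pytest.fixture(scope="session")
def unit_sphere_fine():
    return icosphere_mesh(4)


@pytest.fixture(scope="session")
def sphere_basis(unit_sphere):
    return compute_harmonics(unit_sphere, 40)


@pytest.fixture(scope="session")
def templates():
    return make_templates(CohortSpec())


@pytest.fixture(scope="session")
def bases(templates):
    return compute_bases(templates, 70)


@pytest.fixture(scope="session")
def effect_cohort(bases, templates):
    """Default study-condition cohort: 45/23, planted 1.0 mm bilateral
    harmonic effect (2x the 0.5 mm subject-level smooth SD)."""
    from subshape.synthetic_data import simulate_cohort

    return simulate_cohort(CohortSpec(seed=11), bases, templates)


@pytest.fixture(scope="session")
def null_cohort(bases, templates):
    from subshape.synthetic_data import simulate_cohort

    return simulate_cohort(
        CohortSpec(seed=12, effect_amplitude_mm=0.0), bases, templates
    )
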
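import numpy as np
import pytest

from connectoprofile.io import Cohort, ConnectivityMatrix, NodeTable
from connectoprofile.synthetic import LesionSpec, generate_study, preset_config


@pytest.fixture(scope="session")
def tiny_study():
    """A 10-node, 6-control synthetic study with a one-node lesion."""
    cfg = preset_config("tiny10", seed=42)
    return generate_study(cfg, lesion=LesionSpec(target_nodes=[2], attenuation=0.3))


@pytest.fixture(scope="session")
def tiny_cohort(tiny_study):
    return Cohort(
        controls=tiny_study["controls"],
        patient=tiny_study["patient"],
        node_table=tiny_study["nodes"],
    )


@pytest.fixture
def triangle():
    """Triangle with weights w_AB=1, w_BC=2, w_AC=3."""
    return ConnectivityMatrix(
        weights=np.array([[0.0, 1, 3], [1, 0, 2], [3, 2, 0]]), subject_id="tri"
    )


@pytest.fixture
def path3():
    """3-node path A-B-C with unit weights."""
    return ConnectivityMatrix(
        weights=np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]]), subject_id="path3"
    )


@pytest.fixture
def collinear_nodes():
    """Three collinear nodes at x = 0, 1, 2 (for navigation walks)."""
    return NodeTable(
        labels=["a", "b", "c"],
        hemispheres=["midline"] * 3,
        coords=np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]),
    )


def make_manifest(tmp_path, study):
    """Write a study to disk and return the manifest path."""
    from connectoprofile.synthetic import write_study

    return write_study(study, tmp_path / "study")
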
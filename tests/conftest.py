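import numpy as np
import pytest

from geofunc.features import FeatureManifest, featurize, dummy_embedder
from geofunc.model import ModelConfig, FunctionPredictor
from geofunc.synthetic import synthetic_backbone


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation matrix via QR with sign fix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


@pytest.fixture(scope="session")
def mixed_backbone():
    """30-residue helix/strand/coil backbone with mild coordinate jitter."""
    return synthetic_backbone([("helix", 14), ("strand", 8), ("coil", 8)],
                              seed=3, jitter=0.2)


@pytest.fixture(scope="session")
def small_manifest():
    return FeatureManifest(embed_dim=16, k_neighbors=8,
                           embed_name="dummy-16-s0")


@pytest.fixture(scope="session")
def mixed_graph(mixed_backbone, small_manifest):
    return featurize(mixed_backbone, dummy_embedder(16), small_manifest)


@pytest.fixture(scope="session")
def small_model(small_manifest):
    from geofunc.gvp import GnnConfig
    cfg = ModelConfig.for_manifest(
        small_manifest, n_classes=3, seed=7,
        gnn=GnnConfig(node_dims=(32, 4), n_layers=2, msg_depth=2,
                      out_scalar_dim=32, dropout=0.1),
        n_super=8, n_heads=4)
    return FunctionPredictor(cfg)
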
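import numpy as np
import pytest

import decoyrank as dr


@pytest.fixture(scope="session")
def toy_complex():
    """Stylized AVGSYVYSV / groove complex (all peptide heavy atoms)."""
    return dr.make_toy_complex("AVGSYVYSV", seed=1)


@pytest.fixture(scope="session")
def decoy_set(toy_complex):
    """20 perturbed decoys of the toy complex with measured HA RMSDs."""
    decoys, achieved = dr.perturb_decoys(toy_complex, n=20, spread=0.6, seed=2)
    return decoys, achieved


@pytest.fixture(scope="session")
def small_suite():
    """Feature-level suite: 6 targets x 60 decoys, linear plant."""
    return dr.generate_feature_suite(
        dr.EnsembleSpec(n_targets=6, n_decoys=60, seed=3)
    )


def rigid_motion(rng):
    """Random proper rotation + translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.normal(scale=5.0, size=3)
    return rot, trans
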
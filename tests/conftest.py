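import numpy as np
import pytest

from cortarch import gli, io, quant, synthetic


@pytest.fixture(scope="session")
def density_fixture():
    """Packaged 33-area x 14-receptor mean/SD density tables."""
    return io.load_density_fixture()


@pytest.fixture
def ligand():
    """Hand-picked but physically plausible counting constants."""
    return quant.LigandParams(E=0.4, B=2.0, W_b=0.05, S_a=80.0, K_D=1.0, L=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ribbon_features(spec: synthetic.RibbonSpec, n_depth: int = 101) -> np.ndarray:
    """Full generator -> traverses -> profiles -> features pipeline."""
    image, contours, _ = synthetic.make_ribbon(spec)
    traverses = gli.build_traverses(contours, spec.n_profiles)
    profiles = [gli.sample_profile(image, t, n_depth=n_depth, index=i)
                for i, t in enumerate(traverses)]
    return gli.featurize_ribbon(profiles)


@pytest.fixture
def flat_ribbon_spec():
    base = np.full(32, 30.0)
    return synthetic.RibbonSpec(
        n_profiles=160, border_positions=(80,),
        laminar_means=(base, base + 12.0), noise_sd=4.0, seed=7)
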
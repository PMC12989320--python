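import numpy as np
import pytest

from unidose import ObjectiveConfig, PhantomSpec, generate_phantom, make_label_dose


def small_spec(seed: int = 42, **overrides) -> PhantomSpec:
    """Desk-test phantom spec: 24^3 grid (4.8 cm cube at 2 mm), 5 beams."""
    kw = dict(
        seed=seed,
        grid_shape=(24, 24, 24),
        body_semiaxes_range_mm=((16.0, 20.0), (16.0, 20.0), (18.0, 21.0)),
        target_radius_range_mm=(6.0, 9.0),
        oar_radius_range_mm=(4.0, 7.0),
        n_beams_range=(5, 5),
        n_oars_range=(1, 1),
        prescription_range_gy=(20.0, 60.0),
        p_sib=0.0,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def small_case():
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def small_label(small_case):
    dose, result = make_label_dose(
        small_case, ObjectiveConfig(max_iter=100, tol=1e-5)
    )
    return dose


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
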
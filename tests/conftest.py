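import pytest

from cedkit.datasets import load_cohort_table, load_infusion_table
from cedkit.phantom import PhantomSpec, generate_phantom
from cedkit.survival import read_survival_table


@pytest.fixture(scope="session")
def cohort_records():
    return read_survival_table(load_cohort_table())


@pytest.fixture(scope="session")
def infusion_table():
    return load_infusion_table()


@pytest.fixture(scope="session")
def small_spec():
    """A compact phantom for fast imaging tests (32^3 grid)."""
    return PhantomSpec(
        grid_shape=(32, 32, 32),
        tumor_center_mm=(16.0, 16.0, 16.0),
        tumor_radii_mm=(10.0, 9.0, 8.0),
        infusate_center_mm=(16.0, 16.0, 16.0),
        infusate_radii_mm=(6.0, 5.5, 5.0),
        reference_center_mm=(5.0, 26.0, 26.0),
        reference_radii_mm=(3.5, 3.5, 3.5),
    )


@pytest.fixture(scope="session")
def noiseless_case(small_spec):
    import dataclasses

    spec = dataclasses.replace(small_spec, noise_sigma=0.0)
    return generate_phantom(spec, seed=7)
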
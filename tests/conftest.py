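import pytest

from padckit import synthetic


@pytest.fixture(scope="session")
def clean_dataset():
    """Six linker families, two members each, no within-family divergence."""
    specs = synthetic.default_demo_specs(n_members=2, within_divergence=0.0)
    return synthetic.generate_dataset(specs, global_seed=7)


@pytest.fixture(scope="session")
def diverged_dataset():
    """Six linker families, three members each, 0.15 within-family divergence."""
    specs = synthetic.default_demo_specs(n_members=3, within_divergence=0.15)
    return synthetic.generate_dataset(specs, global_seed=11)


@pytest.fixture(scope="session")
def padc_template():
    """Reference-length PadC scaffold (relative linker length 0, no EAL)."""
    spec = synthetic.FamilySpec("ref0", relative_linker_length=0)
    return synthetic.build_template(spec, rng_seed=5)


@pytest.fixture(scope="session")
def padc_eal_dead_template():
    """PadC-EAL scaffold with degenerate EAF motif and scrambled DDFGTG."""
    spec = synthetic.FamilySpec("ealm7", relative_linker_length=-7,
                                has_eal=True, pde_active=False)
    return synthetic.build_template(spec, rng_seed=6)


@pytest.fixture(scope="session")
def padc_eal_active_template():
    """Catalytically competent PadC-EAL scaffold (EAL + intact DDFGTG)."""
    spec = synthetic.FamilySpec("ealp0", relative_linker_length=0,
                                has_eal=True, pde_active=True)
    return synthetic.build_template(spec, rng_seed=8)
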
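import numpy as np
import pytest

from qaop.dataset import CompoundRecord, DNTDataset, build_design_matrices
from qaop.synthetic import GeneratorConfig, simulate_dataset


def make_record(i: int, **overrides) -> CompoundRecord:
    """A fully observed record with deterministic, valid values."""
    base = dict(
        name=f"cmp-{i}",
        cas_rn=f"100-{i:02d}-5",
        smiles="CCO",
        dtxsid=f"DTXSID{i:07d}",
        dnt_label=i % 2,
        logd=1.0 + 0.5 * i,
        bbb=i % 2,
        cbrain_cblood=0.5 + 0.1 * i,
        pgp_substrate=(i + 1) % 2,
        pgp_inhibitor=i % 2,
        pgp_active=(i // 2) % 2,
        bdnf_label=i % 2,
        syn_label=(i + 1) % 2,
        syn_viability=80.0 - i,
        syn_ec30=1.0 + i,
        nnf_label=i % 2,
        nnf_viability=70.0 + i,
        nnf_ec50min=0.5 + 0.25 * i,
        nnf_ec50max=2.0 + 0.5 * i,
    )
    base.update(overrides)
    return CompoundRecord(**base)


@pytest.fixture
def clean_dataset() -> DNTDataset:
    return DNTDataset([make_record(i) for i in range(6)], provenance="test fixture")


@pytest.fixture(scope="session")
def complete_8() -> DNTDataset:
    """The 8-compound complete-case fixture, generated with missingness 0."""
    ds, _ = simulate_dataset(GeneratorConfig(n_compounds=8, seed=808))
    return ds


@pytest.fixture(scope="session")
def small_fit():
    """One cached small complete-data fit shared by cheap posterior tests."""
    from qaop.model import MCMCConfig, build_model, fit_posterior

    ds, true = simulate_dataset(GeneratorConfig(n_compounds=25, seed=42))
    dm = build_design_matrices(ds)
    model = build_model(dm)
    ps = fit_posterior(model, MCMCConfig(seed=4242, chains=2, warmup=300, draws=300))
    return ds, true, dm, model, ps
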
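import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from vigimech.icsr import DrugProfile
from vigimech.phenotypes import harmonise_phenotypes
from vigimech.synthetic import (
    SynthConfig,
    generate_admet_table,
    generate_cohort,
    make_catalog,
)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def cohort():
    """Mid-sized synthetic cohort with ground truth (fixed seed)."""
    cases, truth = generate_cohort(SynthConfig(n_cases=800, seed=11))
    return cases, truth


@pytest.fixture(scope="session")
def cases(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def truth(cohort):
    return cohort[1]


@pytest.fixture(scope="session")
def catalog_frame():
    cfg = SynthConfig(n_cases=800, seed=11)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(6)[0])
    return make_catalog(cfg, rng)


@pytest.fixture(scope="session")
def catalog(catalog_frame):
    """Drug name -> DrugProfile map covering the antiviral catalog."""
    return {
        r.drug: DrugProfile(drug=r.drug, drug_class=r.drug_class, mw=r.mw)
        for r in catalog_frame.itertuples(index=False)
    }


@pytest.fixture(scope="session")
def full_catalog(cases, catalog):
    """Catalog covering every active in the cohort (comeds classed 'other')."""
    out = dict(catalog)
    for c in cases:
        for d in c.all_actives:
            out.setdefault(d, DrugProfile(drug=d, drug_class="other", mw=300.0))
    return out


@pytest.fixture(scope="session")
def pmap(cases):
    return harmonise_phenotypes(cases)


@pytest.fixture(scope="session")
def admet(catalog_frame):
    return generate_admet_table(catalog_frame, seed=13, missing_frac=0.1)
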
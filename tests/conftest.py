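import numpy as np
import pandas as pd
import pytest

from splicemr.psi import PsiMatrix, compute_psi_table, support_mask
from splicemr.simulate import (SimulationConfig, simulate_genotypes,
                               simulate_splicing)


@pytest.fixture(scope="session")
def ref_config():
    """Small unrelated reference panel: 200 samples, 4 events."""
    return SimulationConfig(seed=7, n_families=100, offspring_range=(0, 0),
                            n_events=4, variants_per_window=30,
                            cis_r2=0.4, n_causal_variants_per_event=2)


@pytest.fixture(scope="session")
def ref_cohort(ref_config):
    panel, ped = simulate_genotypes(ref_config)
    counts, truth = simulate_splicing(panel, ref_config, pedigree=ped)
    psi = compute_psi_table(counts, truth.events)
    support = support_mask(counts, genotyped=panel.samples)
    return {"config": ref_config, "panel": panel, "pedigree": ped,
            "counts": counts, "truth": truth,
            "psi": PsiMatrix(psi=psi, support=support)}


@pytest.fixture(scope="session")
def family_config():
    """Family cohort with a real trait effect of psi_hat."""
    return SimulationConfig(seed=21, n_families=150, offspring_range=(1, 3),
                            n_events=2, variants_per_window=15,
                            cis_r2=0.4, n_causal_variants_per_event=2,
                            psi_effect_on_trait=6.0, trait_kind="binary",
                            family_effect_sd=0.5)


@pytest.fixture(scope="session")
def family_cohort(family_config):
    from splicemr.simulate import simulate_phenotypes

    panel, ped = simulate_genotypes(family_config)
    counts, truth = simulate_splicing(panel, family_config, pedigree=ped)
    pheno = simulate_phenotypes(truth, family_config)
    return {"config": family_config, "panel": panel, "pedigree": ped,
            "truth": truth, "phenotypes": pheno}
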
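import warnings

import pytest

from asmscan.simulate import (
    ArraySimConfig,
    BsAmpliconSpec,
    BsSimConfig,
    simulate_array_experiment,
    simulate_bisulfite_experiment,
)

# the pipeline legitimately warns about floored intensities and small MNR
# counts in miniature fixtures; keep test output readable
warnings.filterwarnings("ignore", message=".*floored before log2.*")
warnings.filterwarnings("ignore", message=".*MNR scores.*")


@pytest.fixture(scope="session")
def array_sim_small():
    """A small mixed-truth array experiment shared across unit tests."""
    cfg = ArraySimConfig(n_samples=20, n_mpr=300, n_mnr=200, n_reference=60,
                         cis_asm_fraction=0.15, random_asm_fraction=0.05,
                         penetrance=0.9, seed=0)
    return simulate_array_experiment(cfg)


@pytest.fixture(scope="session")
def array_stages_small(array_sim_small):
    from asmscan.pipeline import run_array_stages

    return run_array_stages(array_sim_small)


@pytest.fixture(scope="session")
def bs_sim_small():
    """Two-amplicon bisulfite experiment: one differential, one null."""
    amps = [
        BsAmpliconSpec("ampDiff", n_cpg=4, msre_flags=[True, False, True, False],
                       snp_maf=0.4, meth_prob_ref=0.9, meth_prob_alt=0.1,
                       array_a_allele="ref"),
        BsAmpliconSpec("ampNull", n_cpg=3, msre_flags=[True, True, False],
                       snp_maf=0.3, meth_prob_ref=0.8, meth_prob_alt=0.8,
                       array_a_allele="alt"),
    ]
    cfg = BsSimConfig(n_samples=30, amplicons=amps,
                      reads_per_sample_amplicon=60, seed=2)
    return simulate_bisulfite_experiment(cfg)
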
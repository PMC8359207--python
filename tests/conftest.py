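import numpy as np
import pandas as pd
import pytest

from dualsip import (
    FractionRecord,
    GradientProfile,
    OTUCountTable,
    SimulationConfig,
    TreatmentPair,
    make_truth,
    simulate_pair,
)

# density window wide enough that every band of the GC 0.3-0.7 x MWE 0-1
# grid sits >= 3 band-sigmas inside the gradient (no tail truncation)
WIDE_RANGE = (1.650, 1.800)


def make_profile(
    incubation_id="INC_U",
    substrate="DOM",
    isotope="unlabelled",
    densities=(1.74, 1.72, 1.70, 1.68, 1.66),
    totals=(100.0, 500.0, 900.0, 400.0, 100.0),
    **kwargs,
):
    fractions = [
        FractionRecord(
            sample_id=f"{incubation_id}_F{i + 1:02d}",
            incubation_id=incubation_id,
            fraction_index=i + 1,
            density=d,
            total_copies=t,
        )
        for i, (d, t) in enumerate(zip(densities, totals))
    ]
    return GradientProfile(
        incubation_id=incubation_id,
        substrate=substrate,
        isotope=isotope,
        fractions=fractions,
        **kwargs,
    )


@pytest.fixture
def profile():
    return make_profile()


@pytest.fixture
def treatment_pair():
    return TreatmentPair(
        unlabelled=make_profile("INC_U", isotope="unlabelled"),
        labelled=make_profile("INC_L", isotope="labelled"),
    )


@pytest.fixture
def tiny_counts():
    df = pd.DataFrame(
        [[5, 0], [1, 2], [0, 7]],
        index=["OTU_1", "OTU_2", "OTU_3"],
        columns=["S1", "S2"],
    )
    taxonomy = {
        "OTU_1": "Bacteria;Proteobacteria;Gammaproteobacteria",
        "OTU_2": "Bacteria;Cyanobacteria;Oxyphotobacteria",
        "OTU_3": "Archaea;Euryarchaeota;Thermoplasmata",
    }
    return OTUCountTable(counts=df, taxonomy=taxonomy)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Analytic, noise-free simulated pair on a truth grid (exact inverse)."""
    cfg = SimulationConfig(
        n_otus=36,
        density_range=WIDE_RANGE,
        reads_per_sample=100_000,
        qpcr_cv=0.0,
        analytic=True,
        seed=123,
    )
    rng = np.random.default_rng(cfg.seed)
    truth = make_truth(cfg.n_otus, rng, abundance_sigma=0.0)
    return simulate_pair(cfg, truth)


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-noise simulated pair (multinomial reads, 10% qPCR CV)."""
    cfg = SimulationConfig(
        n_otus=60,
        density_range=WIDE_RANGE,
        reads_per_sample=50_000,
        seed=42,
    )
    rng = np.random.default_rng(cfg.seed)
    truth = make_truth(cfg.n_otus, rng, mwe_values=(0.0, 0.05, 0.3, 0.5))
    return simulate_pair(cfg, truth)
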
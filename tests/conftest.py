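import numpy as np
import pytest

from vitdmr import GRSWeights, VariantSummary, load_instrument_fixture
from vitdmr.synthetic_data import calibrate_genetic_effects, scenario


@pytest.fixture(scope="session")
def instrument():
    """The bundled six-variant 25-OHD instrument, already oriented."""
    return load_instrument_fixture()


@pytest.fixture(scope="session")
def grs_weights():
    """Calibrated per-allele weights matching the default generator."""
    cfg = scenario("null")
    betas, _ = calibrate_genetic_effects(cfg)
    return GRSWeights(variant_ids=tuple(cfg.variant_ids), weights=tuple(betas))


def random_variants(rng: np.random.Generator, k: int) -> list[VariantSummary]:
    """Random but well-formed harmonized summary rows for property tests."""
    x = rng.uniform(0.01, 0.1, k)
    sy = rng.uniform(0.005, 0.03, k)
    y = rng.normal(0.0, 0.02, k)
    return [
        VariantSummary(
            variant_id=f"rs{i}",
            beta_exposure=float(x[i]),
            se_exposure=float(rng.uniform(0.001, 0.005)),
            beta_outcome=float(y[i]),
            se_outcome=float(sy[i]),
        )
        for i in range(k)
    ]
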
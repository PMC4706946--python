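import numpy as np
import pytest

import exomeqc as eq
from exomeqc.simdata import COMMON_MAF_SPECTRUM

ALL_ERROR_MODES = (
    ("ab_misassign", 0.05),
    ("low_r_wide_theta", 0.05),
    ("short_boundary", 0.05),
)


@pytest.fixture(scope="session")
def clean_bundle():
    """A clean mid-sized cohort under the default MAF spectrum."""
    return eq.simulate_dataset(eq.SimConfig(n_samples=200, n_variants=150, seed=42))


@pytest.fixture(scope="session")
def error_bundle():
    """A cohort with all three misclassification modes planted."""
    return eq.simulate_dataset(eq.SimConfig(
        n_samples=300, n_variants=120, seed=7, error_mode_rates=ALL_ERROR_MODES))


@pytest.fixture(scope="session")
def error_stack(error_bundle):
    """Built models (short-boundary shrink applied), calls, metrics and
    adjusted-ruleset flags for the error bundle."""
    shrink = set(error_bundle.error_variants("short_boundary"))
    model = eq.build_cluster_models(error_bundle.intensities,
                                    shrink_variants=shrink)
    calls = eq.call_genotypes(error_bundle.intensities, model)
    table = eq.metrics_table(calls, error_bundle.intensities, model)
    report = eq.apply_ruleset(table, eq.builtin_ruleset("adjusted"))
    return {"model": model, "calls": calls, "metrics": table, "flags": report}


@pytest.fixture(scope="session")
def related_bundle():
    """Common-MAF cohort with one duplicate and one parent-offspring
    pair, enough polymorphic variants for IBD."""
    return eq.simulate_dataset(eq.SimConfig(
        n_samples=24, n_variants=5000, maf_spectrum=COMMON_MAF_SPECTRUM,
        x_chrom_fraction=0.0, dup_pairs=1, rel_pairs=1, seed=3))
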
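import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from ribodms.reference import (
    BUILTIN_NAMES,
    RibozymeReference,
    load_builtin,
    parse_structure,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_ref() -> RibozymeReference:
    """A 12-nt reference with a 2-bp stem, a 1-bp pseudoknot, one catalytic site."""
    seq = "GCAGACUACUGC"
    regions = parse_structure("((.[....].))", {"H1": "S1", "H2": "T"})
    return RibozymeReference(
        name="toy",
        sequence=seq,
        leader="GGAU",
        paired_regions=regions,
        catalytic_positions=frozenset({5}),
    )


@pytest.fixture(scope="session", params=BUILTIN_NAMES)
def shipped_ref(request) -> RibozymeReference:
    return load_builtin(request.param)


@pytest.fixture(scope="session")
def twister_ref() -> RibozymeReference:
    return load_builtin("twister")


def binomial_counts_table(ref, model, depth, seed, replicates=3):
    """Direct per-genotype binomial counts at fixed depth (no read emission)."""
    from ribodms.reference import WT, enumerate_double_mutants, enumerate_single_mutants
    from ribodms.simulate import true_relative_activity

    rng = np.random.default_rng(seed)
    rows = []
    for g in [WT] + enumerate_single_mutants(ref) + enumerate_double_mutants(ref):
        ra = true_relative_activity(ref, g, model)
        fc = min(1.0, model.wt_fc * ra)
        for r in range(1, replicates + 1):
            c = int(rng.binomial(depth, fc))
            rows.append((str(g), f"rep{r}", c, depth - c))
    return pd.DataFrame(
        rows, columns=["genotype", "replicate", "n_cleaved", "n_uncleaved"]
    )
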
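"""Shared fixtures: a compact locus (2-kb element, 300-bp LTRs) keeps the
unit suite fast; geometry is otherwise identical to the default fixture."""

import pytest

from petalsplit.simdata import SimParams, simulate_allele_pair, simulate_locus

SMALL = dict(te_len=2000, ltr_len=300)


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    return SimParams(**SMALL)


@pytest.fixture(scope="session")
def locus(small_params):
    return simulate_locus(small_params, seed=1)


@pytest.fixture(scope="session")
def allele_pair():
    return simulate_allele_pair(seed=5)
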
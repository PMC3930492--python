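import pytest

from mdfkit import (
    ChainSpec,
    ConcentrationConstraints,
    chain_constraints,
    make_chain,
)


@pytest.fixture
def symmetric_4chain():
    """Four identical -4 kJ/mol steps, terminals fixed at 1 M, wide
    intermediate bounds: MDF = 4, every reaction shadow price 0.25."""
    spec = ChainSpec(dg0=(-4.0,) * 4, c_start=1.0, c_end=1.0)
    return spec, make_chain(spec), chain_constraints(spec)


@pytest.fixture
def two_chain_bound_limited():
    """A -> B -> C with dG0 = 0; A and C on default 1 uM - 10 mM bounds,
    B wide.  Optimum: A at upper bound, C at lower, B interior;
    w = (0.5, 0.5) and metabolite shadow price of A = 0.5."""
    spec = ChainSpec(dg0=(0.0, 0.0))
    pathway = make_chain(spec)
    cons = ConcentrationConstraints(default_lower=1e-6, default_upper=1e-2)
    cons.set_bound("C1", lower=1e-9, upper=1e3)
    return pathway, cons
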
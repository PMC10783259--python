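import hypothesis.strategies as st
import pytest
from hypothesis import settings

from plastattr import (
    Basis,
    ChemicalUseProfile,
    PlasticityClass,
    UseShare,
    datasets,
)

settings.register_profile("deterministic", derandomize=True, max_examples=60)
settings.load_profile("deterministic")


@st.composite
def use_shares(draw, basis):
    plasticity = draw(st.sampled_from(list(PlasticityClass)))
    override = None
    if plasticity is PlasticityClass.PARTIAL and draw(st.booleans()):
        override = draw(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0]))
    return UseShare(
        category=draw(st.text(min_size=1, max_size=8)),
        share_value=draw(st.one_of(st.just(0.0), st.floats(0.1, 1000.0, allow_nan=False))),
        basis=basis,
        plasticity=plasticity,
        partial_fraction_override=override,
    )


@st.composite
def profiles(draw, min_rows=1, max_rows=8):
    """Random valid use profiles with at least one strictly positive share."""
    basis = draw(st.sampled_from(list(Basis)))
    shares = draw(st.lists(use_shares(basis), min_size=min_rows, max_size=max_rows))
    if not any(s.share_value > 0 for s in shares):
        positive = draw(st.floats(0.1, 1000.0, allow_nan=False))
        shares.append(
            UseShare(
                category="anchor",
                share_value=positive,
                basis=basis,
                plasticity=draw(st.sampled_from(list(PlasticityClass))),
            )
        )
    return ChemicalUseProfile(chemical_id="HYP", shares=tuple(shares))


@pytest.fixture(scope="session")
def reference_prfs():
    return datasets.reference_prfs()


@pytest.fixture(scope="session")
def burden_rows():
    return datasets.load_burden_table()
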
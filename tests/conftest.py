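import hypothesis
import pytest

from phenocapture import FieldBook, FixtureSpec, Options, make_fieldbook

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=30, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def tiny_spec():
    """2 plots x 1 row x 3 plants, one descriptor per trait type."""
    return FixtureSpec(plots=2, rows_per_plot=1, plants_per_row=3, seed=42)


@pytest.fixture
def tiny_book(tiny_spec) -> FieldBook:
    return make_fieldbook(tiny_spec)


@pytest.fixture
def zigzag_book(tiny_spec) -> FieldBook:
    return make_fieldbook(tiny_spec, options=Options(zigzag=True))
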
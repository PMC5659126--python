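import copy

import pytest

from bofsens.lp import fva
from bofsens.model import set_active_biomass
from bofsens.sensitivity import condition_flux_ranges
from bofsens.synthetic import core_constraints, make_core_fixture


@pytest.fixture(scope="session")
def _core_built():
    return make_core_fixture()


@pytest.fixture()
def core(_core_built):
    """Fresh copy of (model, compositions, phenotypes) per test."""
    model, comps, phen = _core_built
    return copy.deepcopy(model), comps, dict(phen)


@pytest.fixture()
def core_model(core):
    return core[0]


@pytest.fixture(scope="session")
def met_gly_ranges(_core_built):
    """FVA allowable ranges per composition under the co-feed condition.

    Session-scoped: FVA over all 12 compositions is the most expensive
    fixture step and the result is read-only.
    """
    model, comps, _ = _core_built
    model = copy.deepcopy(model)
    return condition_flux_ranges(
        model, comps, core_constraints("met_gly"), gamma=1.0
    )
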
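"""Shared pytest fixtures."""

from __future__ import annotations

import pytest

from odna_retention import ModelParameters, StaticEnvironment


@pytest.fixture
def reference_params():
    """Moderately damaged organelle-encoded gene with typical yeast rates."""
    return ModelParameters(synthesis_rate=1.0, transport_rate=1.0,
                           degradation_organelle=0.5,
                           degradation_cytosol=0.1,
                           wildtype_fraction=0.75)


@pytest.fixture
def unit_static():
    return StaticEnvironment(a=1.0)
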
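import numpy as np
import pytest

from morphoreg import (
    DeformationProtocol,
    PhantomSpec,
    ShapeParams,
    apply_serial_deformation,
    generate_phantom_stack,
)


@pytest.fixture(scope="session")
def default_params() -> ShapeParams:
    """A mid-grid shape-model setting with visible but modest deformation."""
    return ShapeParams(alpha=1000.0, beta=0.1)


@pytest.fixture(scope="session")
def phantom_stack():
    """Small aligned phantom reused by read-only tests."""
    spec = PhantomSpec(n_sections=4, height=224, width=224, n_tubes=6, seed=11)
    return generate_phantom_stack(spec)


@pytest.fixture(scope="session")
def translated_phantom(phantom_stack):
    """The same phantom after small per-section translations (no rotation)."""
    protocol = DeformationProtocol(
        kind="fib-sem", rotation_deg=0.0, shift_px=5.0, mls_every=0
    )
    return apply_serial_deformation(phantom_stack, protocol, seed=23)
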
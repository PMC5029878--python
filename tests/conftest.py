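import numpy as np
import pytest

from musclefat.phantom import FieldSpec, PhantomSpec


@pytest.fixture
def small_spec() -> PhantomSpec:
    """A fast 96x96 single-slice phantom for reconstruction tests."""
    return PhantomSpec(
        grid_shape=(96, 96),
        n_slices=1,
        compartment_radius=18.0,
        bone_radius=4.0,
        subcutaneous_ring=4.0,
    )


@pytest.fixture
def flat_field() -> FieldSpec:
    """Zero receiver and field phase (no phase errors at all)."""
    return FieldSpec(
        phase0_coeffs=np.array([[0.0]]),
        phase_per_echo_coeffs=np.array([[0.0]]),
    )


def uniform_ff_spec(base: PhantomSpec, ff: float) -> PhantomSpec:
    """Copy of a phantom spec with the same true f.f. in every muscle."""
    return PhantomSpec(
        **{**base.__dict__, "muscle_ff_true": {lab: ff for lab in range(1, 11)}}
    )
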
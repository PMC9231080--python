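import numpy as np
import pytest

import thzamino as tz


@pytest.fixture(scope="session")
def instr0() -> tz.InstrumentSpec:
    """Noise-free instrument."""
    return tz.InstrumentSpec(noise_sigma_single=0.0)


@pytest.fixture(scope="session")
def instr_noisy() -> tz.InstrumentSpec:
    return tz.InstrumentSpec()


@pytest.fixture(scope="session")
def library() -> list[tz.MaterialSpec]:
    return tz.build_material_library()


@pytest.fixture(scope="session")
def ref_trace(instr0) -> tz.TimeTrace:
    return tz.simulate_reference(instr0)


@pytest.fixture(scope="session")
def slab_175() -> tz.MaterialSpec:
    """Dispersion-free slab with n = 1.75, the worked-example material."""
    return tz.MaterialSpec("slab", (), eps_inf=1.75**2, baseline_slope=0.0)


@pytest.fixture(scope="session")
def roundtrip_noise_free(library, instr0, ref_trace):
    """Noise-free, echo-free extraction for every library class, with the
    programmed optical constants evaluated on the same band."""
    from thzamino.forward_model import C_MM_PS

    out = []
    for mat in library:
        trace = tz.simulate_sample_trace(mat, instr0, n_echoes=0)
        oc = tz.extract_optical_constants(trace, ref_trace, mat.thickness_d)
        n_true, kappa = tz.complex_refractive_index(mat, oc.f)
        alpha_true = 2.0 * (2.0 * np.pi * oc.f) * kappa / C_MM_PS
        out.append((mat, oc, n_true, alpha_true))
    return out
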
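import pytest

from morphosynth.phantom import (
    DEFAULT_TISSUES,
    PhantomGeometry,
    TissueParameterTable,
    TissueParams,
    build_phantom,
)


@pytest.fixture(scope="session")
def geometry32():
    return PhantomGeometry.create((32, 32, 32))


@pytest.fixture(scope="session")
def geometry48():
    return PhantomGeometry.create((48, 48, 48))


@pytest.fixture(scope="session")
def phantom32(geometry32):
    """Noise-free piecewise-constant phantom on a small grid."""
    return build_phantom(geometry32, DEFAULT_TISSUES, rng_seed=0)


@pytest.fixture(scope="session")
def phantom48(geometry48):
    return build_phantom(geometry48, DEFAULT_TISSUES, rng_seed=0)


@pytest.fixture(scope="session")
def three_tissue_table():
    """Tissue table with all GM subclasses identical, so any synthetic image
    has exactly three distinct intensities (CSF, GM, WM)."""
    gm = TissueParams(r1=0.72, pd=0.83, r2s=16.0)
    return TissueParameterTable(
        {
            "wm": DEFAULT_TISSUES["wm"],
            "cortical_gm": gm,
            "sensorimotor_gm": gm,
            "nucleus_gm": gm,
            "csf": DEFAULT_TISSUES["csf"],
        }
    )
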
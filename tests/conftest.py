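import numpy as np
import pytest

from vsfpm import forward, optics, phantom, recon, register


@pytest.fixture(scope="session")
def system() -> optics.OpticalSystem:
    """The 4x/0.16 objective + 200 mm tube lens + large-format camera."""
    return optics.OpticalSystem()


@pytest.fixture(scope="session")
def led_array() -> optics.LEDArray:
    return optics.LEDArray()


@pytest.fixture(scope="session")
def plan177(led_array, system) -> optics.LEDPlan:
    return optics.build_led_plan(led_array, system, n_leds=177)


@pytest.fixture(scope="session")
def small_setup(system, plan177):
    """150x150 object grid / 50x50 sensor grid capture geometry."""
    pupil = optics.make_pupil(system, plan177.wavelength, (50, 50), 0.9)
    return {"pupil": pupil, "pixel_size": 0.3, "shape": (150, 150), "ds": 3}


class FieldObject:
    """Minimal complex-transmission carrier for capture_stack."""

    def __init__(self, field, pixel_size):
        self.field = field
        self.pixel_size = pixel_size
        self.shape = field.shape


@pytest.fixture(scope="session")
def bandlimited_phantom(system, plan177, small_setup):
    """Phantom band-limited to the synthetic NA: exact inverse-crime truth."""
    ph = phantom.generate_phantom(shape=small_setup["shape"],
                                  pixel_size=small_setup["pixel_size"],
                                  n_crypts=1, seed=2)
    na_syn = optics.synthetic_na(system, plan177)
    cut = na_syn / (plan177.wavelength * 1e-3)
    fld = recon.bandlimit(ph.field, ph.pixel_size, cut)
    return FieldObject(fld, ph.pixel_size), na_syn


@pytest.fixture(scope="session")
def noiseless_stack(plan177, small_setup, bandlimited_phantom):
    obj, _ = bandlimited_phantom
    return forward.capture_stack(obj, plan177, small_setup["pupil"],
                                 downsample_factor=small_setup["ds"],
                                 noise_params=forward.NoiseParams.none(), seed=0)


@pytest.fixture(scope="session")
def smoke_pairs():
    """16 registered 64-px training pairs from one phantom."""
    ph = phantom.generate_phantom(shape=(256, 256), pixel_size=0.4, n_crypts=2, seed=5)
    st = phantom.render_hne(ph)
    pairs = []
    for i in range(4):
        for j in range(4):
            sl = (slice(i * 64, (i + 1) * 64), slice(j * 64, (j + 1) * 64))
            pairs.append(register.PatchPair(ph.phase[sl], st.rgb[sl],
                                            mi_score=1.0, accepted=True,
                                            coords=(i * 64, j * 64)))
    return pairs


@pytest.fixture(scope="session")
def phantom256():
    return phantom.generate_phantom(shape=(256, 256), pixel_size=0.4, n_crypts=2, seed=3)
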
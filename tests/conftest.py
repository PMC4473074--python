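import numpy as np
import pytest

from gangliomsi.chem import build_panel
from gangliomsi.msi_io import SpectralImage
from gangliomsi.simulate import EffectConfig


@pytest.fixture(scope="session")
def panel():
    return build_panel()


@pytest.fixture
def noiseless_config():
    """Generator configuration with every stochastic term switched off."""
    return EffectConfig(noise_sigma=0.0, gain_sigma=0.0)


def grid_image(nx=8, ny=6, mz=None, fill=1.0, pitch=100.0):
    """Small continuous-mode image with constant spectra, for geometry tests."""
    if mz is None:
        mz = np.linspace(1000.0, 1010.0, 101)
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    intens = np.full((len(coords), mz.size), float(fill))
    return SpectralImage(coordinates=coords, mz_axis=mz, intensities=intens, pitch_um=pitch)


@pytest.fixture
def small_image():
    return grid_image()
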
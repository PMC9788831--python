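import numpy as np
import pytest

from seamsta import build_lattice, make_spec, render
from seamsta.tomo import add_noise, apply_wedge


@pytest.fixture(scope="session")
def spec13_3():
    return make_spec(13, 3)


@pytest.fixture(scope="session")
def single_seam_lattice(spec13_3):
    """A 176-nm 13_3 tube with the canonical single seam at contact 0."""
    return build_lattice(spec13_3, {0}, 176.0)


@pytest.fixture(scope="session")
def clean_render(single_seam_lattice):
    """Noise-free decorated render of the single-seam tube."""
    return render(single_seam_lattice)


@pytest.fixture(scope="session")
def corrupted_render(clean_render):
    """The same render behind a +/-60 degree wedge at SNR 3."""
    vol, gt = clean_render
    return add_noise(apply_wedge(vol, 60.0, "single"), 3.0, seed=42), gt


def random_valid_lattice(rng, length=200.0):
    """A random closed lattice over the valid N_S range with random seams."""
    n = int(rng.integers(8, 18))
    s = int(rng.choice([2, 3, 4]))
    k = s % 2 + 2 * int(rng.integers(0, (n - s % 2) // 2 + 1))
    seams = set(map(int, rng.choice(n, size=k, replace=False)))
    return build_lattice(make_spec(n, s), seams, length)
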
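import numpy as np
import pytest

from phunlattice import (
    Atom,
    AtomicModel,
    Chain,
    DensityVolume,
    NoiseSpec,
    Residue,
    make_subunit_motif,
    preset_spec,
    render_lattice_image,
)


@pytest.fixture(scope="session")
def motif():
    """Default asymmetric subunit motif used across lattice tests."""
    return make_subunit_motif(seed=3)


@pytest.fixture(scope="session")
def p2_image(motif):
    """Noisy p2 micrograph at the in vitro cell (120 Å, 100°), SNR 0.3."""
    img, truth = render_lattice_image(
        preset_spec("p2-invitro"), motif, image_size=1024, pixel_size=4.0,
        noise=NoiseSpec(snr=0.3, seed=7),
    )
    return img, truth


@pytest.fixture(scope="session")
def p4_image(motif):
    """Noisy p4 micrograph at the square in vitro cell, SNR 0.3."""
    img, truth = render_lattice_image(
        preset_spec("p4-invitro"), motif, image_size=1024, pixel_size=4.0,
        noise=NoiseSpec(snr=0.3, seed=11),
    )
    return img, truth


@pytest.fixture(scope="session")
def sphere_volume():
    """Centered smooth sphere, 64³ at 2 Å/voxel."""
    n, vx = 64, 2.0
    zz, yy, xx = (np.mgrid[0:n, 0:n, 0:n] - n / 2 + 0.5) * vx
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    return DensityVolume(np.clip(1.0 - (r / 40.0) ** 2, 0, None) ** 2, vx)


def make_ca_chain(chain_id: str, coords, start: int = 1) -> Chain:
    residues = [
        Residue(start + i, "ALA", "", [Atom("CA", "C", np.asarray(x, float))])
        for i, x in enumerate(coords)
    ]
    return Chain(chain_id, residues)


def make_ca_model(coords_by_chain: dict, regions=None) -> AtomicModel:
    chains = [make_ca_chain(cid, xyz) for cid, xyz in coords_by_chain.items()]
    return AtomicModel(chains=chains, regions=regions or {})
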
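import numpy as np
import pytest

import couplekit as ck


@pytest.fixture(scope="session")
def default_params():
    return ck.DEFAULT_PARAMS


@pytest.fixture(scope="session")
def long_chain():
    """Chain long enough that the first 60 cells behave as an infinite chain
    (the reflecting far end doubles the tail excess near the boundary only)."""
    return ck.CellLattice.chain(130)


@pytest.fixture(scope="session")
def centered_hex():
    """Regular hexagonal mosaic with a single central probe cell."""
    lat = ck.generate_mosaic(ck.MosaicSpec(n_cells=900, jitter_sd=0.0,
                                           probe_fraction=0.002, seed=0))
    pos = lat.positions
    center = int(np.argmin(np.linalg.norm(pos - pos.mean(axis=0), axis=1)))
    return lat.with_probes([center])


def params_for_ratio(q: float, bg_frac: float = 0.1) -> ck.ModelParams:
    """ModelParams with k_out/D = q, C0 = 100 and background fraction bg_frac."""
    D = 1.0
    k_out = q * D
    k_in = bg_frac * 100.0 * k_out / 40.0 if k_out > 0 else 0.0
    return ck.ModelParams(D=D, k_out=k_out, k_in=k_in, C_solution=40.0, C0=100.0)
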
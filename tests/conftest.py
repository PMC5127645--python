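import numpy as np
import pytest

from organoidquant.synthgen import OrganoidSimParams, make_organoid_stack


@pytest.fixture(scope="session")
def small_stack():
    """One deterministic two-channel stack with truth, shared across tests."""
    params = OrganoidSimParams(
        stack_shape=(96, 96, 12), n_alive=15, n_dead=5, pi_channel=True, seed=4
    )
    stack, truth = make_organoid_stack(params)
    return params, stack, truth


def midpoint_threshold(params: OrganoidSimParams) -> float:
    """Threshold halfway between background level and blob peak."""
    return params.background_level * (1 + params.snr) / 2


def flood_fill_components(mask2d: np.ndarray, connectivity: int) -> list[set]:
    """Independent 2D connected-components oracle via explicit BFS flood fill."""
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    seen = np.zeros_like(mask2d, dtype=bool)
    comps = []
    ny, nx = mask2d.shape
    for sy in range(ny):
        for sx in range(nx):
            if mask2d[sy, sx] and not seen[sy, sx]:
                comp = set()
                queue = [(sy, sx)]
                seen[sy, sx] = True
                while queue:
                    y, x = queue.pop()
                    comp.add((y, x))
                    for dy, dx in neigh:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < ny and 0 <= xx < nx and mask2d[yy, xx] and not seen[yy, xx]:
                            seen[yy, xx] = True
                            queue.append((yy, xx))
                comps.append(comp)
    return comps
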
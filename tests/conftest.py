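"""Shared fixtures and independent oracles for the test suite."""

from collections import deque

import numpy as np
import pytest

from tauscope import synthetic


def flood_fill_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Independent connected-components labeling by BFS flood fill."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]
    labels = np.zeros((h, w), dtype=np.int64)
    current = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                queue = deque([(r, c)])
                labels[r, c] = current
                while queue:
                    rr, cc = queue.popleft()
                    for dr, dc in offsets:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] \
                                and labels[nr, nc] == 0:
                            labels[nr, nc] = current
                            queue.append((nr, nc))
    return labels


@pytest.fixture()
def clean_inclusion():
    """A noise-free inclusion field with (3, 2, 1) deposits and its ledger."""
    spec = synthetic.InclusionFieldSpec(seed=42, noise_sd=0.0,
                                        n_particles_per_class=(3, 2, 1))
    stack, truth = synthetic.generate_inclusion_field(spec)
    return spec, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
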
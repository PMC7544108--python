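"""Shared fixtures: small synthetic panels and annotations.

Everything is generated at test time from fixed seeds; no data files.
"""

import numpy as np
import pytest

from otomap.annotations import AnnotationMatrix
from otomap.sim import gen_reference_panel, plant_truth


@pytest.fixture(scope="session")
def small_panel():
    """1000 individuals x 2000 variants, heterogeneous LD blocks of 20."""
    return gen_reference_panel(
        1000, 2000, 20, (0.0, 0.9), spacing_bp=10_000, seed=42
    )


@pytest.fixture(scope="session")
def small_annotations(small_panel):
    rng = np.random.default_rng(7)
    mask = np.zeros(small_panel.n_variants, dtype=bool)
    blocks = rng.choice(small_panel.n_blocks, 5, replace=False)
    L = small_panel.block_length
    for b in blocks:
        mask[b * L : (b + 1) * L] = True
    return AnnotationMatrix.from_masks({"ocr": mask})


@pytest.fixture(scope="session")
def base_truth(small_panel):
    return plant_truth(
        AnnotationMatrix.base_only(small_panel.n_variants), 0.3, seed=11
    )
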
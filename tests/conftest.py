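import numpy as np
import pandas as pd
import pytest

import bsrwalk.synthetic as syn


@pytest.fixture(scope="session")
def small_reference():
    """200 kb single-chromosome reference with 12 genes."""
    return syn.make_reference([200_000], 12, seed=11)


@pytest.fixture(scope="session")
def small_map(small_reference):
    return syn.make_genetic_map(
        small_reference, 60, centromere_span=(80_000, 120_000),
        suppression_factor=0.1, cm_per_mb=5.0, seed=12,
    )


def make_linked_map(distances_cm, unlinked=0):
    """Map with markers at given cM distances from a causal marker at
    chr1:1000, plus optionally markers on an unlinked chromosome."""
    cm = [0.0] + [float(d) for d in distances_cm]
    bp = [1_000 * (i + 1) for i in range(len(cm))]
    frames = [pd.DataFrame({"chrom": "chr1", "pos_bp": bp, "pos_cm": cm})]
    if unlinked:
        frames.append(
            pd.DataFrame(
                {
                    "chrom": "chr2",
                    "pos_bp": [1_000 * (i + 1) for i in range(unlinked)],
                    "pos_cm": [0.0] * unlinked,
                }
            )
        )
    return syn.GeneticMap(pd.concat(frames, ignore_index=True))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
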
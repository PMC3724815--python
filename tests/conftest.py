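"""Shared fixtures: hand-built alignments and session-scoped synthetic tables."""

from __future__ import annotations

import pytest

from mirforest import (
    AlignConfig,
    DuplexAlignment,
    PairCategory,
    RFConfig,
    SyntheticConfig,
    generate_feature_table,
    train_forest,
)

# canonical residue pair for each category (mirna_char, target_char)
CATEGORY_RESIDUES = {
    PairCategory.GC_MATCH: ("G", "C"),
    PairCategory.AU_MATCH: ("A", "U"),
    PairCategory.GU_WOBBLE: ("G", "U"),
    PairCategory.MISMATCH: ("A", "C"),
    PairCategory.GAP: ("A", "-"),
}


def make_alignment(categories, score=0.0, mfe=None) -> DuplexAlignment:
    """Build an alignment whose columns realize the requested categories."""
    mrow = "".join(CATEGORY_RESIDUES[c][0] for c in categories)
    trow = "".join(CATEGORY_RESIDUES[c][1] for c in categories)
    n_t = sum(1 for ch in trow if ch != "-")
    return DuplexAlignment(
        mirna_row=mrow,
        target_row=trow,
        score=score,
        target_start=1,
        target_end=n_t,
        mfe=mfe,
    )


@pytest.fixture(scope="session")
def align_cfg():
    return AlignConfig()


@pytest.fixture(scope="session")
def small_table():
    """Quick labeled table for classifier unit tests (default conditions, small n)."""
    return generate_feature_table(SyntheticConfig(n_pos=40, n_neg=40, rng_seed=5))


@pytest.fixture(scope="session")
def small_forest(small_table):
    return train_forest(small_table, RFConfig(n_trees=200, rng_seed=5))


@pytest.fixture(scope="session")
def main_table():
    """The default study conditions: n_pos = n_neg = 200, fixed seed."""
    return generate_feature_table(SyntheticConfig(rng_seed=1))
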
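import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from pairedcna.profiles_io import GenomeLayout, SegmentedProfile


@pytest.fixture
def toy_layout():
    """Three small chromosomes for hand-checkable cases."""
    return GenomeLayout((("chr1", 100_000), ("chr2", 80_000), ("chr3", 50_000)))


@pytest.fixture
def autosomes_22():
    """22 equal 1 Mb chromosomes (fast WGD-rule checks)."""
    return GenomeLayout(tuple((f"chr{i}", 1_000_000) for i in range(1, 23)))


def build_profile(layout, segments, sample_id="S1", **kwargs):
    """segments: iterable of (chrom, start, end, total_cn, minor_cn)."""
    df = pd.DataFrame(
        list(segments), columns=["chromosome", "start", "end", "total_cn", "minor_cn"]
    )
    return SegmentedProfile(sample_id, df, layout, **kwargs)


@pytest.fixture
def make_profile():
    return build_profile


def uniform_profile(layout, total_cn, minor_cn, sample_id="S1"):
    """Whole-genome constant-state profile."""
    segs = [(c, 0, layout.length(c), total_cn, minor_cn) for c in layout.names]
    return build_profile(layout, segs, sample_id=sample_id)


@pytest.fixture
def make_uniform():
    return uniform_profile
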
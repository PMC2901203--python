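import numpy as np
import pytest

from gfmap.ld_simulator import StudyData


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_study(mat, pat, y=None, positions=None, **kw) -> StudyData:
    """Build a StudyData from raw arrays with a default 0.1 cM grid."""
    mat = np.asarray(mat, dtype=np.uint8)
    if positions is None:
        positions = np.arange(mat.shape[1]) * 0.1
    return StudyData(
        maternal_haplotypes=mat,
        paternal_haplotypes=np.asarray(pat, dtype=np.uint8),
        positions_cM=np.asarray(positions, dtype=float),
        y=None if y is None else np.asarray(y, dtype=float),
        **kw,
    )


def random_study(rng, n=40, n_markers=5, with_y=True) -> StudyData:
    mat = rng.integers(0, 2, (n, n_markers))
    pat = rng.integers(0, 2, (n, n_markers))
    y = rng.normal(size=n) if with_y else None
    return make_study(mat, pat, y)
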
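import numpy as np
import pytest

from linkanchor import simulate as S

SMALL_PRESET = dict(
    n_chrom=3,
    length_bp_per_chrom=3_000_000,
    mean_scaffold_bp=400_000,
    min_scaffold_bp=50_000,
    n_markers=60,
    n_lines=119,
)


@pytest.fixture(scope="session")
def small_dataset():
    """3 chromosomes x 3 Mbp, 60 markers, 119 DH lines."""
    return S.simulate_dataset(seed=7, **SMALL_PRESET)


@pytest.fixture(scope="session")
def small_map_and_hits(small_dataset):
    from linkanchor import anchoring as A, linkage as L

    ds = small_dataset
    seqs = {s.id: s.sequence for s in ds.scaffolds}
    hits = A.align_markers(ds.markers, seqs)
    lmap = L.build_map(
        ds.genotypes,
        anchors={m.id: m.truth_chrom for m in ds.markers if m.type == "SSR"},
        anchor_cm={m.id: m.truth_cM for m in ds.markers if m.type == "SSR"},
    )
    return ds, lmap, hits


def make_dh_calls(r, n_lines, rng):
    """Two call vectors for loci at recombination fraction r."""
    a = rng.integers(0, 2, size=n_lines)
    rec = rng.random(n_lines) < r
    b = np.where(rec, 1 - a, a)
    sym = np.array(["A", "B"])
    return sym[a], sym[b]
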
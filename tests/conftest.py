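import numpy as np
import pytest
from hypothesis import settings

from cnvgwas import CnvCall, DetectionConfig, SimConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic small cohort exercising every reader and the pipeline."""
    cfg = SimConfig(n_subjects=120, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture
def three_subject_calls():
    """The hand-checkable loss overlap: A [100,300], B [200,400], C [200,300]."""
    return [
        CnvCall("A", "1", 100, 300, -1),
        CnvCall("B", "1", 200, 400, -1),
        CnvCall("C", "1", 200, 300, -1),
    ]


def brute_force_sub_cnvrs(calls, n_subjects, threshold):
    """Independent per-segment detector: no sweeping, direct containment tests.

    For every segment between consecutive distinct event positions, a subject
    is a carrier iff any of its calls fully covers the segment on the
    half-open scale.  Segments with carrier fraction strictly above the
    threshold are reported, exactly like the production detector's contract.
    """
    out = []
    for chrom in sorted({c.chromosome for c in calls}):
        on = [c for c in calls if c.chromosome == chrom]
        positions = sorted({p for c in on for p in (c.start_pos, c.end_pos)})
        subjects = sorted({c.subject_id for c in on})
        for left, right in zip(positions, positions[1:]):
            carriers = frozenset(
                s for s in subjects
                if any(c.subject_id == s and c.start_pos <= left and c.end_pos >= right
                       for c in on)
            )
            if len(carriers) / n_subjects > threshold:
                out.append((chrom, left, right, carriers))
    return out


def random_instance(rng, max_subjects=20, max_positions=60, max_cnvs=6):
    """A random small CNV call set on a discrete position grid."""
    n_subjects = int(rng.integers(2, max_subjects + 1))
    grid = np.sort(rng.choice(np.arange(1, 10 * max_positions, 10),
                              size=max_positions, replace=False))
    calls = []
    for i in range(n_subjects):
        for _ in range(int(rng.integers(0, max_cnvs + 1))):
            a, b = sorted(rng.choice(len(grid), size=2, replace=False))
            state = int(rng.choice([-2, -1, 1, 2]))
            calls.append(
                CnvCall(f"S{i}", str(rng.integers(1, 3)), int(grid[a]), int(grid[b]),
                        state, n_snps=int(b - a + 1))
            )
    return calls, n_subjects
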
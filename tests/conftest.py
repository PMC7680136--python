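import pytest

from palcat.detect import DetectionParams, find_palindromes
from palcat.seqio import GenomeSequence
from palcat.synthdata import simulate_cohort, write_cohort


@pytest.fixture(scope="session")
def fig_example() -> GenomeSequence:
    """The canonical 8-bp worked example: GACA followed by its reverse
    complement TGTC."""
    return GenomeSequence(name="chrT", bases="GACATGTC")


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """A simulated cohort with one plant per effect class, written to disk."""
    sim = simulate_cohort(n_events=10, seed=11)
    paths = write_cohort(sim, tmp_path_factory.mktemp("cohort"))
    return sim, paths


@pytest.fixture(scope="session")
def cohort_ref_pals(cohort):
    sim, _ = cohort
    return find_palindromes(sim.reference, DetectionParams())
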
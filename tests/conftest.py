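import pytest

from aedsx.simulate import LocusConfig, simulate_locus

EXON_CLASSES_8 = [
    "common", "common", "common", "common",
    "female_specific", "female_specific", "male_specific", "utr",
]


@pytest.fixture(scope="session")
def small_locus():
    """An 8-exon gene with short introns, pure-pyrimidine acceptors and
    perfect donors: every junction statistic is forced."""
    config = LocusConfig(
        exon_sizes=[60, 45, 48, 60, 50, 50, 80, 40],
        exon_classes=EXON_CLASSES_8,
        intron_sizes=[150, 120, 200, 90, 60, 100, 130],
        acceptor_p=1.0,
        donor_fidelity=6,
    )
    return simulate_locus(config, seed=11)
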
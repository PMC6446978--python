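import logging

import numpy as np
import pytest

from fnregulon import (
    GeneAnnotation, GenomeRecord, SyntheticScenario, reverse_complement,
)

# keep expected-warning chatter (empty promoters etc.) out of test output
logging.getLogger("fnregulon").setLevel(logging.ERROR)


@pytest.fixture
def small_genome() -> GenomeRecord:
    """3-kb single-contig genome with three genes used by coordinate tests.

    Layout: gA (+) 201-400, gB (+) 1001-1600, gC (-) 1701-2000.
    """
    rng = np.random.default_rng(42)
    contig = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))
    genes = [
        GeneAnnotation("gA", "c1", 201, 400, "+"),
        GeneAnnotation("gB", "c1", 1001, 1600, "+"),
        GeneAnnotation("gC", "c1", 1701, 2000, "-"),
    ]
    return GenomeRecord("tiny", {"c1": contig}, genes)


@pytest.fixture
def scenario() -> SyntheticScenario:
    return SyntheticScenario(seed=0)


def consensus_agreement(found: str, planted: str, max_shift: int = 1) -> float:
    """Fraction of planted consensus columns matched by the recovered
    consensus, maximized over strand and a small phase shift (the standard
    alignment-tolerant comparison for discovered motifs)."""
    w = len(planted)
    best = 0.0
    for cand in (found, reverse_complement(found)):
        for shift in range(-max_shift, max_shift + 1):
            n = sum(
                1
                for j in range(w)
                if 0 <= j + shift < w and cand[j + shift] == planted[j]
            )
            best = max(best, n / w)
    return best
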
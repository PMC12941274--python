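import pytest

from zfam import synthetic_data as synth


@pytest.fixture(scope="session")
def small_genome():
    """A 3-chromosome genome with one planted family covering every
    duplication mode, plus its hit table and ledger."""
    genome, ledger = synth.simulate_genome(
        synth.GenomeConfig(n_chrom=3, genes_per_chrom=20), seed=11
    )
    genome, hits, ledger = synth.plant_family(
        genome,
        ledger,
        "famA",
        ["tandem", "tandem", "proximal", "dispersed"],
        seed=1,
    )
    return genome, hits, ledger


def naive_scan_count(sequence: str, iupac: str) -> int:
    """Test-local brute-force non-overlapping scan oracle."""
    from zfam.promoter_cis import IUPAC_TO_BASES

    sets = [IUPAC_TO_BASES[c] for c in iupac.upper()]
    L = len(sets)
    seq = sequence.upper()
    i = count = 0
    while i + L <= len(seq):
        if all(seq[i + j] in sets[j] for j in range(L)):
            count += 1
            i += L
        else:
            i += 1
    return count
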
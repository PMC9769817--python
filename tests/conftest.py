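import pytest

from cbestop import GenomeSimParams, fixture_bundle, generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A 20 kb single-contig genome carrying 12 clean ORFs."""
    params = GenomeSimParams(
        contig_length=20_000, n_genes=12, gene_length_range=(60, 150), seed=1
    )
    genome, genes, ledger = generate_genome(params)
    return genome, genes, ledger


@pytest.fixture(scope="session")
def single_edit_bundle(tmp_path_factory):
    """On-disk single-edit-strain scenario bundle (FASTA/GFF3/VCFs/TSV)."""
    out = tmp_path_factory.mktemp("bundle")
    truth = fixture_bundle(out, scenario="single-edit", seed=3)
    return out, truth
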
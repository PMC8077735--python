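import numpy as np
import pytest

from carbsite import seqio, synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_fasta(tmp_path):
    path = tmp_path / "proteins.fa"
    path.write_text(">p1\nMKTACDKACDWY\n>p2\nKACD\n")
    return path


@pytest.fixture
def small_proteins(small_fasta):
    return seqio.read_fasta(small_fasta)


@pytest.fixture
def synthetic_dataset(tmp_path):
    """A small motif-planted dataset written to disk: (fasta, sites) paths."""
    cfg = synthdata.GeneratorConfig(
        n_proteins=15, residue="K", positive_fraction=0.35,
        enrichment_strength=0.9, seed=11,
    )
    fasta_text, tsv_text = synthdata.generate(cfg)
    fasta = tmp_path / "synth.fa"
    sites = tmp_path / "synth.tsv"
    fasta.write_text(fasta_text)
    sites.write_text(tsv_text)
    return fasta, sites


def random_peptide(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWYX"):
    return "".join(rng.choice(list(alphabet), size=length))
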
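import numpy as np
import pytest

from hetflag.synthetic_data import SimulationSpec, simulate_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared by read-only tests."""
    spec = SimulationSpec(n_lnc=200, n_mrna=200, seed=7)
    matrix, truth = simulate_matrix(spec)
    return spec, matrix, truth


def write_gtf(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


def gtf_exon(chrom, start1, end1, strand, gene, tx, extra=""):
    """One GTF exon line, 1-based inclusive coordinates."""
    attrs = f'gene_id "{gene}"; transcript_id "{tx}";' + extra
    return f"{chrom}\ttest\texon\t{start1}\t{end1}\t.\t{strand}\t.\t{attrs}"
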
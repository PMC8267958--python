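import numpy as np
import pytest

from tlsburden import MutationMatrix

MAF_HEADER = (
    "Hugo_Symbol\tChromosome\tStart_Position\tEnd_Position\t"
    "Reference_Allele\tTumor_Seq_Allele2\tVariant_Classification\t"
    "Tumor_Sample_Barcode"
)


def write_maf_text(path, rows, header=MAF_HEADER, pragma="#version 2.4"):
    """Write a toy MAF from (gene, chrom, start, end, ref, alt, cls, sample) tuples."""
    lines = [pragma, header] if pragma else [header]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def maf_writer(tmp_path):
    def _write(name, rows, **kwargs):
        return write_maf_text(tmp_path / name, rows, **kwargs)

    return _write


def random_matrix(n_genes, n_samples, density, seed):
    """Seeded random boolean incidence matrix used as a toy cohort."""
    rng = np.random.default_rng(seed)
    incidence = rng.random((n_genes, n_samples)) < density
    return MutationMatrix(
        genes=[f"G{i}" for i in range(n_genes)],
        samples=[f"S{j}" for j in range(n_samples)],
        incidence=incidence,
    )


@pytest.fixture
def toy_matrix_factory():
    return random_matrix
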
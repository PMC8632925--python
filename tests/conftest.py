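import numpy as np
import pytest

from orgfusion.records import OrfRecord
from orgfusion.study import synthetic_study


@pytest.fixture(scope="session")
def bundle():
    """One full synthetic study shared by the read-only tests."""
    return synthetic_study(seed=11)


@pytest.fixture(scope="session")
def cms_orf_sets(bundle):
    from orgfusion.orfs import find_orfs

    out = {}
    for line, genome in bundle.cms.items():
        orfs = []
        for contig in genome.contigs:
            found = find_orfs(contig, min_nt=75)
            for o in found:
                o.line_id = line
            orfs.extend(found)
        out[line] = orfs
    return out


def gene_orfs(genome, line_id=None):
    """Annotated genes of a genome as OrfRecords (for clustering tests)."""
    out = []
    for ann in genome.genes:
        nt = genome.gene_sequence(ann.gene_id)[:-3]  # drop the stop codon
        aa_len = len(nt) // 3
        out.append(
            OrfRecord(
                ann.gene_id, ann.contig_id, ann.start, ann.end, ann.strand,
                nt, "M" + "A" * (aa_len - 1), line_id=line_id or genome.line_id,
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
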
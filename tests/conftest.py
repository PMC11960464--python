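import pytest

from genestrata.core_data import Cohort, GeneRecord, Phylostratum
from genestrata.synthetic_cohort import CohortConfig, generate_cohort


def make_gene(gene_id, branch="old", chrom="1", ops=(), **kw):
    ops = frozenset(ops)
    defaults = dict(
        symbol=gene_id,
        chromosome=chrom,
        start=100,
        end=200,
        protein_length=400.0,
        gene_length=12000.0,
        branch=branch,
        dnv_burden=1.0,
        rare_burden=2.0,
        is_disease=int(bool(ops)),
        op_set=ops,
    )
    defaults.update(kw)
    return GeneRecord(gene_id=gene_id, **defaults)


@pytest.fixture
def three_strata():
    return (
        Phylostratum("old", "Old", 400.0),
        Phylostratum("mid", "Mid", 200.0),
        Phylostratum("young", "Young", 50.0),
    )


@pytest.fixture
def small_cohort(three_strata):
    genes = [
        make_gene("g1", "old", "1", ("OP1",)),
        make_gene("g2", "old", "1", ("OP1", "OP2")),
        make_gene("g3", "old", "2"),
        make_gene("g4", "mid", "2", ("OP7",), repro_class="male"),
        make_gene("g5", "mid", "X"),
        make_gene("g6", "young", "X", ("OP1", "OP7"), repro_class="female"),
    ]
    return Cohort(genes, phylostrata=three_strata)


@pytest.fixture(scope="session")
def generated_cohort():
    """One generated cohort shared across tests, sized so that roughly 10^4
    disease genes are available for distributional checks."""
    cohort, truth = generate_cohort(CohortConfig(n_genes=40_000, seed=11))
    return cohort, truth
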
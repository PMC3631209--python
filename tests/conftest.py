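import pytest

from mqfpcr.homolog_finder import find_homologous_pairs
from mqfpcr.primer_design import design_assay
from mqfpcr.synth_data import ParalogGenomeSpec, make_paralog_genome


@pytest.fixture(scope="session")
def planted_delta5():
    """Genome with a planted homologous pair (identity 0.95, delta 5) plus
    the recovered pair and a designed assay, shared across modules."""
    genome, truth = make_paralog_genome(ParalogGenomeSpec(identity=0.95, delta=5, seed=7))
    pairs = find_homologous_pairs(genome[0], genome)
    assert pairs, "planted pair not recovered"
    assays = design_assay(pairs[0])
    assert assays, "no assay designed for planted pair"
    return {"genome": genome, "truth": truth, "pair": pairs[0], "assay": assays[0]}


@pytest.fixture(scope="session")
def planted_delta2():
    genome, truth = make_paralog_genome(ParalogGenomeSpec(identity=0.95, delta=2, seed=11))
    pairs = find_homologous_pairs(genome[0], genome)
    assert pairs
    assays = design_assay(pairs[0])
    assert assays
    return {"genome": genome, "truth": truth, "pair": pairs[0], "assay": assays[0]}
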
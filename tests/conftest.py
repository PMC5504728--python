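import pytest

from hlacheck.allele_db import (
    AlleleDefinition,
    AlleleName,
    AlleleTable,
    SnpMarker,
)
from hlacheck.genotype_io import GenotypePosterior, IndividualGenotypes


@pytest.fixture
def worked_marker() -> SnpMarker:
    """The single C/G marker of the canonical worked example."""
    return SnpMarker(
        id="rs41541913", gene="HLA-A", cdna_pos=1, strand="+",
        alleleA="C", alleleB="G",
    )


@pytest.fixture
def worked_table(worked_marker) -> AlleleTable:
    """Two-allele table: A*01:01 carries G, A*80:01 carries C."""
    a0101 = AlleleDefinition(
        name=AlleleName.parse("A*01:01"), bases={worked_marker.id: "G"})
    a8001 = AlleleDefinition(
        name=AlleleName.parse("A*80:01"), bases={worked_marker.id: "C"})
    return AlleleTable(gene="HLA-A", markers=(worked_marker,),
                       alleles=(a0101, a8001))


@pytest.fixture
def worked_individual(worked_marker) -> IndividualGenotypes:
    """Posteriors 10% CC, 65% CG, 25% GG at the worked-example marker."""
    return IndividualGenotypes(
        individual_id="ind1",
        posteriors={worked_marker.id: GenotypePosterior(
            p_AA=0.10, p_AB=0.65, p_BB=0.25)},
    )
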
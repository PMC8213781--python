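import pytest

from ecisminer.model import CoreConfig, GeneRecord


@pytest.fixture
def config() -> CoreConfig:
    return CoreConfig.default()


@pytest.fixture
def gene_factory():
    """Terse GeneRecord constructor for hand-built scaffolds."""

    def make(
        gene_id,
        start,
        end,
        scaffold="s1",
        genome="G1",
        strand="+",
        pfams=(),
        cogs=(),
        coding=True,
    ) -> GeneRecord:
        return GeneRecord(
            gene_id=gene_id,
            genome_id=genome,
            scaffold_id=scaffold,
            start=start,
            end=end,
            strand=strand,
            is_protein_coding=coding,
            pfams=frozenset(pfams),
            cogs=frozenset(cogs),
        )

    return make
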
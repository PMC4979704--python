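import numpy as np
import pytest

import panmix
from panmix.synthetic import GeneratorSpec, generate, table2_frequencies


@pytest.fixture(scope="session")
def panel():
    return table2_frequencies()


@pytest.fixture(scope="session")
def panmictic_table():
    """Study-sized null dataset: 159 samples in 55/55/49 groups, 32 loci."""
    table, truth = generate(GeneratorSpec(mode="panmictic", seed=11))
    return table, truth


@pytest.fixture(scope="session")
def panmictic_dosage(panmictic_table):
    table, _ = panmictic_table
    return panmix.to_dosage(table)


@pytest.fixture()
def tiny_tsv(tmp_path):
    """Hand-written 3-sample, 2-locus genotype file plus locus sidecar."""
    geno = tmp_path / "tiny.tsv"
    geno.write_text(
        "sample_id\thabitat\tbatch\tlocA\tlocB\n"
        "fish1\tlittoral\t1\tAC\tGG\n"
        "fish2\tbenthic\t1\tAA\tNA\n"
        "fish3\tpelagic\t2\tCC\tGT\n"
    )
    loci = tmp_path / "tiny.loci.tsv"
    loci.write_text("locus_id\tlinkage_group\nlocA\t3\nlocB\t7\n")
    return geno, loci
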
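import pytest

import germline_reset as gr

# shared study design: a pre-migratory stage with reactivated (XCR) females,
# an earlier stage with inactive-X (XCI) females, and a somatic compartment
DESIGN = [
    ("pgc", 30, "F", "XCR"),
    ("pgc", 30, "M", "male"),
    ("early", 30, "F", "XCI"),
    ("early", 30, "M", "male"),
    ("soma", 15, "F", "XCI"),
    ("soma", 15, "M", "male"),
]


@pytest.fixture(scope="session")
def thr():
    return gr.Thresholds()


@pytest.fixture(scope="session")
def genome():
    return gr.simulate_genome(11, "tiny")


@pytest.fixture(scope="session")
def sizes_no_y(genome):
    return {c: s for c, s in genome.chrom_sizes.items() if c != "Y"}


@pytest.fixture(scope="session")
def expr_bundle(genome):
    """Clean expression bundle (no QC failures / contaminants)."""
    return gr.simulate_expression(genome, DESIGN, 12, qc_fail_frac=0.0)


@pytest.fixture(scope="session")
def allelic_table(genome, expr_bundle):
    _, _, truth = expr_bundle
    return gr.simulate_allelic_counts(genome, truth, 13)


@pytest.fixture(scope="session")
def methylomes(genome):
    tables, truth = gr.simulate_methylome(
        genome, [("PGC_F", "PGC", "F"), ("soma_F", "soma", "F")], 14
    )
    return tables, truth
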
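"""Allelic-resolution evidence for X reactivation.

Simulates read counts at X-linked SNVs (XCI cells transcribe one haplotype,
XCR cells both), applies the SNV filters (validated sites, >=3 reads,
recurrent in >=2 cells per stage), calls mono-/biallelic status, derives the
somatic "escaper" gene set, and counts biallelic non-escaper genes per cell.
"""

import germline_reset as gr
import germline_reset.allelic as al

thr = gr.Thresholds()
genome = gr.simulate_genome(seed=1, scale="tiny")
design = [
    ("pgc", 30, "F", "XCR"),
    ("early", 30, "F", "XCI"),
    ("soma", 15, "F", "XCI"), ("soma", 15, "M", "male"),
]
_, _, truth = gr.simulate_expression(genome, design, seed=6, qc_fail_frac=0.0)
table = gr.simulate_allelic_counts(genome, truth, seed=7, depth=20,
                                   error_rate=0.001)

calls = al.call_allelic_status(al.filter_snvs(table, thr), thr)
kept = calls["kept"].mean()
print(f"{len(calls)} (cell, SNV) records; {kept:.1%} pass the filters")
print("filter reasons:",
      calls.loc[~calls["kept"], "filter_reason"].value_counts().to_dict())

soma_f = truth.cells.index[
    (truth.cells["stage"] == "soma") & (truth.cells["true_sex"] == "F")]
escapers = al.identify_escapers(calls, soma_f)
print(f"somatic escaper genes (biallelic in somatic females): "
      f"{sorted(escapers.index)}")
print(f"planted escaper genes:                                "
      f"{sorted(truth.escaper_genes)}")

females = truth.cells.index[truth.cells["true_sex"] == "F"]
counts = al.count_biallelic_genes(calls, escapers, females)
for state, stage in (("XCR", "pgc"), ("XCI", "early")):
    cells = truth.cells.index[(truth.cells["xc_state"] == state)
                              & (truth.cells["stage"] == stage)]
    sub = counts.reindex(cells)
    print(f"{state} females: mean {sub.mean():.1f} biallelic non-escaper genes; "
          f"{(sub >= 1).mean():.0%} of cells have at least one")
# XCR cells show many biallelically expressed X genes beyond the somatic
# escapers; XCI cells show essentially none - the allelic proof of
# reactivation.
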
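"""Bisulfite methylome analysis: global demethylation, escapee tiles, and
transposable-element enrichment.

Simulates a near-completely demethylated germ-cell methylome (~1%) with 50
planted 800-nt methylation-retaining ("escapee") tiles at ~40%, placed
preferentially over one evolutionarily young SINE family, plus a
hypermethylated somatic methylome (~75%, CpG islands ~10%).
"""

import germline_reset as gr
import germline_reset.methylome as me

thr = gr.Thresholds()  # pig preset: escapee methylation level >= 0.15
genome = gr.simulate_genome(seed=1, scale="tiny")
tables, truth = gr.simulate_methylome(
    genome, [("PGC", "PGC", "F"), ("soma", "soma", "F")], seed=8)
sizes = {c: s for c, s in genome.chrom_sizes.items() if c != "Y"}

for name in ("PGC", "soma"):
    cpgs = tables[name]
    tiles = me.tile_methylation(cpgs, sizes, thr.tile_global)
    print(f"{name}: global weighted methylation "
          f"{100 * me.global_weighted_methylation(cpgs):.2f}%, "
          f"median 1-kb tile {100 * tiles['level'].median():.1f}% "
          f"({len(cpgs)} CpGs)")

esc = me.detect_escapees(tables["PGC"], sizes, thr)
esc = me.classify_te_content(esc, genome.repeats, thr)
called = esc[esc["class"] == "meth+"]
print(f"escapee (meth+) tiles called: {len(called)} "
      f"(planted: {len(truth.escapee_tiles)}); "
      f"TE-rich: {(called['te_class'] == 'TE-rich').sum()}, "
      f"TE-poor: {(called['te_class'] == 'TE-poor').sum()}")

fg = esc[(esc["class"] == "meth+") & (esc["te_class"] == "TE-rich")]
bg = esc[esc["class"] != "uncallable"]
enr = me.te_enrichment(fg, bg, genome.repeats, thr)
print("TE family enrichment among TE-rich escapees "
      "(ES = overlap fraction ratio vs all callable tiles):")
for family, row in enr.iterrows():
    mark = "  <- enriched (ES>2, p<0.001)" if row["enriched"] else ""
    print(f"  {family:>8}: ES {row['es']:6.2f}  p {row['p']:.2e}{mark}")
# only the planted young family should be flagged: demethylation-resistant
# loci cluster over young, active transposons that the germline keeps
# silenced by retaining methylation.
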
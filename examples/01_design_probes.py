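"""Tile 60-mer probes across a promoter window.

Builds one gene anchored at a TSS, derives its 8 kb design window
(5.5 kb upstream, 2.5 kb downstream) and tiles probes at 205 bp average
spacing, printing the layout a tiling array would use for that promoter.
"""

from promtile import GeneModel, design_window, tile_probes

gene = GeneModel(gene_id="mbd3", chrom="chr1", tss=100_000, strand="+")
window = design_window(gene)
probes = tile_probes(window, tss=gene.tss)

starts = [p.start for p in probes]
mean_spacing = (starts[-1] - starts[0]) / (len(starts) - 1)

print(f"window: {window.chrom}:{window.start}-{window.end} ({window.length} bp)")
print(f"probes placed: {len(probes)}")
print(f"first probe offset from TSS: {probes[0].offset_from_tss} bp (negative = upstream)")
print(f"last probe: start {probes[-1].start}, end {probes[-1].end} (flush with window edge)")
print(f"mean start-to-start spacing: {mean_spacing:.1f} bp")
# 40 probes cover the full 8 kb so every base lies within ~205 bp of a probe,
# matching the density of a 244k-feature promoter tiling design.
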
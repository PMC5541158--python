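# TCDB membership snapshot for the packaged KO marker set.
# One KEGG ortholog id per line; KOs not listed are treated as
# non-transporters (closed world). Covers only KOs appearing in
# enriched_ko_markers.tsv.
K01546
K01547
K01548
K03310
K03499
K07301
K03543
K03446
K07799
K06045
K15495
K15496
K14393
K02168
K06213
K05565
K05567
K05568
K05569
K05570
K05571
K14683
K14445
K03451
K03308
K08714
K03975
K08223
K03549
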
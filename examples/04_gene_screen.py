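"""In-silico degenerate-primer screening for NRPS and PKS-II loci.

Plants one marker locus per primer pair, runs in-silico PCR, and then
screens a whole synthetic community. Product sizes are measured 5'-end to
5'-end: 480 bp for the NRPS adenylation-domain pair, 350 bp for the PKS-II
ketosynthase-alpha pair.
"""
from actinoprint import generate_community, insilico_pcr, screen_isolates, screen_summary
from actinoprint.defaults import PRIMER_PAIRS
from actinoprint.synthetic import default_config, plant_marker_locus

for locus, pair in PRIMER_PAIRS.items():
    insert = pair.expected_size - len(pair.forward) - len(pair.reverse)
    template = plant_marker_locus(insert, pair.forward, pair.reverse, rng_seed=1)
    call = insilico_pcr(template, pair)
    (amp,) = call.amplicons
    print(f"{locus:<7} product: {amp.length} bp (expected {pair.expected_size}), "
          f"positive={call.positive}")

config = default_config(seed=7)
config.template_length = 300  # shorter 16S, faster demo
records = generate_community(config)
table = screen_isolates(records, list(PRIMER_PAIRS.values()))
summary = screen_summary(table, {r.isolate_id: r.genus for r in records})
print("\nprevalence (percent of isolates positive per locus):")
print(summary.to_string(index=False))
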
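"""Compute the seven genomic-context features for group pairs.

Generates a small synthetic scenario (genomes carrying group-labelled gene
intervals), builds the occurrence index from the placed-hit table, and
prints feature rows for a few pairs.  High co-occurrence, short average
distance and a high co-orientation fraction are the signatures of a
functionally linked pair.
"""

from phagelink.pair_features import build_feature_table
from phagelink.synthetic_data import SyntheticScenario, generate_scenario

params = SyntheticScenario(
    n_genomes=12, genome_length=40_000, n_interacting_pairs=6, n_background_pvogs=10
)
scenario = generate_scenario(params, seed=42)
index = scenario.index()

interacting = scenario.interacting_pairs[:3]
background = [("VOG0013", "VOG0015"), ("VOG0014", "VOG0016")]
table = build_feature_table(index, scenario.ani, scenario.aai, interacting + background)

print(table.round(3).to_string(index=False))
print(
    "\nThe first rows are planted interacting pairs: near-complete genome "
    "co-occurrence (Jaccard ~1), cassette-scale distances (~10^2 nt) and "
    "mostly co-oriented hits.  The background pairs co-occur rarely and sit "
    "tens of kilobases apart."
)
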
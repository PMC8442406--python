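"""Target-set prediction and guilt-by-association annotation transfer.

Trains a final model on a synthetic scenario, scores every co-occurring
group pair outside the ground truth, summarizes the prediction run and
links unannotated groups to their annotated high-confidence partners.
"""

from phagelink.annotation_text import build_annotation
from phagelink.classifier import DESK_SCALE_SPACE
from phagelink.ground_truth import build_target_set, ground_truth_exclusion
from phagelink.pair_features import build_feature_table
from phagelink.pipeline import prepare_datasets, select_model
from phagelink.prediction import predict_pairs, summarize, top_annotated_pairs
from phagelink.synthetic_data import SyntheticScenario, generate_training_scenario

params = SyntheticScenario(
    n_genomes=15, genome_length=60_000, n_interacting_pairs=20, n_background_pvogs=40
)
training = generate_training_scenario(params, seed=5)
prepared = prepare_datasets(training, seed=5)
result = select_model(prepared, seed=5, n_iter=10, space=DESK_SCALE_SPACE)

scenario = training.scenario
# exclude the positives plus the selected training set's negatives
gt_pairs = ground_truth_exclusion(
    prepared.positives,
    [ds.negatives for ds in prepared.datasets],
    selected=int(result.selected_dataset.lstrip("N")) - 1,
)
target = build_target_set(scenario.pvogs, gt_pairs, prepared.index)
table = build_feature_table(prepared.index, scenario.ani, scenario.aai, target.pairs)
predictions = predict_pairs(result.final_model, table)
annotations = {
    pvog: build_annotation(pvog, raws) for pvog, raws in scenario.annotations.items()
}

summary = summarize(predictions, annotations)
print(f"target pairs scored: {summary['total_pairs']}")
print(
    f"predicted to interact: {summary['predicted_positive']} "
    f"({summary['predicted_positive_pct']}%)"
)
print(
    f"high confidence (p >= {summary['high_confidence_cutoff']}): "
    f"{summary['high_confidence_ge_cutoff']} "
    f"({summary['high_confidence_ge_cutoff_pct']}% of positives)"
)
print(
    f"unannotated groups linked to an annotated partner: "
    f"{summary['unknown_pvogs_linked']} of {summary['unknown_pvogs']} "
    f"({summary['unknown_pvogs_linked_pct']}%)"
)
print("\ntop predicted interactions between annotated groups:")
print(top_annotated_pairs(predictions, annotations, n=5).round(3).to_string(index=False))
print(
    "\nEach linked unannotated group inherits a preliminary functional hint "
    "from its highest-probability annotated partner."
)
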
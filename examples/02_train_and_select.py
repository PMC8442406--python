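"""Model selection across ten balanced datasets.

Builds the ground truth from a synthetic interacting-protein list (20
positives + 20 sampled negatives per dataset, ten datasets), runs the
randomized search with five-fold cross-validation on each dataset's 70%
split, evaluates every candidate on every dataset's 30% holdout, and
selects the configuration with the best mean performance.
"""

from phagelink.classifier import DESK_SCALE_SPACE, feature_importances
from phagelink.pipeline import prepare_datasets, select_model
from phagelink.synthetic_data import SyntheticScenario, generate_training_scenario

params = SyntheticScenario(
    n_genomes=15, genome_length=60_000, n_interacting_pairs=20, n_background_pvogs=40
)
training = generate_training_scenario(params, seed=11)
prepared = prepare_datasets(training, seed=11)
print(f"positives: {len(prepared.positives)}; datasets: {len(prepared.datasets)}")

result = select_model(prepared, seed=11, n_iter=10, space=DESK_SCALE_SPACE)
grid = result.grid[result.grid["candidate"] == result.selected_dataset]
print(f"selected dataset: {result.selected_dataset}")
print(f"mean holdout AUROC across datasets: {grid['auroc'].mean():.3f}")
print(f"mean holdout accuracy across datasets: {grid['accuracy'].mean():.3f}")
print("Gini importances (normalized, descending):")
for name, value in feature_importances(result.final_model):
    print(f"  {name:15s} {value:.3f}")
print(
    "\nAn AUROC near 1 reflects the planted cassette signal; co-occurrence "
    "and average distance should carry most of the importance mass."
)
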
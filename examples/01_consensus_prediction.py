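"""Consensus interface prediction on synthetic predictor tables.

Generates six predictor score tables with a planted interface, converts
them to capped ranks, trains the greedy cutoff trajectory, then predicts
at the heavy-overprediction preset and scores the result.
"""

from cport import (
    SyntheticSpec,
    evaluate_chains,
    greedy_train,
    pooled_partition_ranks,
    predict_consensus,
    preset,
    rank_per_chain,
    simulate_scores,
)
from cport.scores import POOLED_PREDICTORS

# study conditions: 6 chains x 130 residues, 15% interface, weak predictors
spec = SyntheticSpec(seed=42)
tables, labels = simulate_scores(spec)

ranks = {
    name: pooled_partition_ranks(t) if name in POOLED_PREDICTORS else rank_per_chain(t)
    for name, t in tables.items()
}

trajectory = greedy_train(ranks, labels)
early = trajectory.at_size(30)
print(f"greedy trajectory: {len(trajectory)} steps")
print(
    f"  after ~30 selections: sensitivity {early.sensitivity:.2f}, "
    f"specificity {early.specificity:.2f} (base rate of interface residues: 0.15)"
)

prediction = evaluate_chains(predict_consensus(ranks, preset("heavy")), labels)
print("heavy-overprediction preset (the docking default):")
print(f"  predictions per chain: {prediction.mean_predictions_per_chain():.0f}")
print(f"  overall sensitivity:   {prediction.overall_sensitivity:.2f}")
print(f"  overall specificity:   {prediction.overall_specificity:.2f}")
print(f"  chains all-wrong:      {prediction.fraction_all_wrong():.0%}")
print(
    "A specificity well above 0.15 at small selection sizes means the "
    "consensus concentrates true interface residues at the top; the heavy "
    "preset then trades specificity for the high sensitivity docking needs."
)
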
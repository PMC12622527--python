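"""Train a scorer on a synthetic screen and measure its screening power.

Generates a DEKOIS-shaped library (40 actives : 1200 decoys) whose actives
carry a 2-SD mean shift on 5 of 100 features, trains an imbalance-weighted
boosted-tree scorer, and evaluates EF / BEDROC / AUROC on an independent
library from the same distribution.  EF 1% near 31 is the ceiling for this
library shape (13-compound top set, 3.2% base active rate); AUROC near 1
confirms the planted signal is fully recovered.
"""

from ibvs import (SyntheticSpec, TrainingConfig, fit_screen_scorer,
                  gen_screening_library, score_screen, screening_report)

train = gen_screening_library(SyntheticSpec(seed=1, effect_size=2.0))
test = gen_screening_library(SyntheticSpec(seed=2, effect_size=2.0))
print(f"library: {int(train['label'].sum())} actives, "
      f"{int((1 - train['label']).sum())} decoys, "
      f"{train.shape[1] - 2} features")

config = TrainingConfig.desk(seed=42, search_trials=5,
                             max_rounds_search=200, max_rounds_final=400)
model = fit_screen_scorer(train, config)
print(f"search: best trial {model.metadata['best_trial']}, "
      f"validation AUCPR {model.metadata['final_val_aucpr']:.3f}, "
      f"scale_pos_weight {model.metadata['scale_pos_weight']:.1f}")

result = score_screen(model, test)
for name, value in screening_report(result).items():
    print(f"  {name}: {value:.4f}")
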
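"""From raw measurements to model-ready windows, one visit at a time.

Shows the event-anchored hourly time index T (event at T=0), carry-forward
imputation with median fallback, and the fixed 25-hour window with end
padding and minority window-shifting.
"""

import numpy as np

from edewarn.pipeline import prepare_cohort
from edewarn.simulate import SimConfig, simulate_cohort
from edewarn.windowing import WindowingConfig, augment_minority

# longer-stay setting than the default so window shifting has room to act
cohort = simulate_cohort(SimConfig(n_visits=500, prevalence_cpr=0.03,
                                   stay_median_h=18.0, seed=4))
prepared = prepare_cohort(cohort, task="CA")

train = prepared.splits["train"]
pos = [g for g, lab in zip(train.grids, train.labels) if lab]
grid = max(pos, key=lambda g: g.length)
print(f"visit {grid.visit_id}: hourly grid spans T={grid.t_min}..0 "
      f"({grid.length} columns), event label CA={grid.label_ca}")
print(f"observed cells: {grid.observed_mask.sum()} of {grid.observed_mask.size} "
      f"({grid.observed_mask.mean():.0%}); the rest were carried forward or "
      "median-filled")
print("per-channel training medians:",
      {ch.value: round(v, 1) for ch, v in prepared.stats.medians.items()})

cfg = WindowingConfig(max_shift=13)
windows = augment_minority([grid], cfg, labels=[True])
print(f"window-shift augmentation (S={cfg.max_shift}) turned this stay into "
      f"{len(windows)} training windows, shifts k={[w.shift for w in windows]}")
w = windows[0]
print(f"window 0: true_length={w.true_length}, pad_count={w.pad_count}; "
      "the encoders read their output at true_length-1, so the padding is "
      "never seen")
print("tabular one-hot vector length:", prepared.encoder.n_features_)
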
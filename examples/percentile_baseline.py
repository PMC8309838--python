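"""Filter baseline: univariate ANOVA-F percentile selection.

Selects the top fraction of columns by class-association F score and
compares the resulting mask with the ground-truth informative set — the
reference point the evolutionary wrapper selection is judged against.
"""

import numpy as np

import thermoga as tg

spec = tg.SynthSpec(n_exams=160, n_features=50, n_informative=10,
                    effect_size=1.5, seed=0)
data, informative = tg.make_feature_table(spec)

mask = tg.percentile_baseline(data, 0.2)
selected = np.flatnonzero(mask)
overlap = len(set(selected) & set(informative))
print(f"percentile 0.2 -> {mask.sum()} columns: {selected.tolist()}")
print(f"informative columns:    {informative.tolist()}")
print(f"precision: {overlap}/{mask.sum()} = {overlap / mask.sum():.2f}")
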
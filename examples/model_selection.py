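"""Evolve SVM hyperparameter configurations (the "Bucket of Models").

Runs a reduced genetic search on a synthetic feature table and prints the
ten best distinct configurations with their cross-validated AUC fitness.
The full default budget is 140 individuals x 30 generations = 4,200
trained models; here a smaller population keeps the example fast.
"""

import thermoga as tg

spec = tg.SynthSpec(n_exams=60, n_features=18, n_informative=5,
                    effect_size=1.5, seed=7)
data, informative = tg.make_feature_table(spec)
print(f"table: {data.n} exams x {data.d} features "
      f"({len(informative)} informative)\n")

cfg = tg.GAConfig(
    population_size=20, generations=5,
    quotas={"selection": 2, "crossover": 6, "asexual": 3,
            "mutation": 2, "random": 7},
    seed=1,
)
bucket, audit = tg.run_model_selection(data, cfg)

print(f"trained {audit['trained_models']} models "
      f"({cfg.population_size} x {cfg.generations}); "
      f"exhaustive grid would need {tg.count_exhaustive(tg.build_parameter_space()):,}\n")
for i, rm in enumerate(bucket, 1):
    c = rm.config
    print(f"#{i:2d} CV-AUC {rm.fitness:.4f}  {c.kernel:8s} nu={c.nu} "
          f"gamma={c.gamma:g} tol={c.tolerance:g}")
print("\nThe bucket feeds the feature-selection stage as its fitness oracle.")
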
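"""Full pipeline at desk scale: synthesize, search, train, test.

Runs the complete loop — synthetic smear generation, 200/40/40 split at
32x32, and a 5-evaluation Bayesian search where each trial trains a CNN
for 10 epochs — then reports the best trial's validation error and its
held-out test metrics.  Takes a minute or two on one core.
"""

from smearopt import ExperimentConfig, run_optimization

config = ExperimentConfig.fast_profile(seed=1, output_dir="scratch/e2e_demo")
result = run_optimization(config)

print("trial  objective  cbd  learning-rate  momentum  regularization")
for t in result.bo_result.history:
    p = t.point_raw
    print(f"{t.iteration:>5} {t.objective:10.4f} {int(p['cbd']):>4} "
          f"{p['initial_learning_rate']:13.5f} {p['momentum']:9.4f} "
          f"{p['regularization']:15.3e}")

m = result.test_metrics
print(f"\nbest validation error: {result.bo_result.best_objective:.4f} "
      f"(stopped by {result.bo_result.stopped_by})")
print(f"held-out test set:  sensitivity {m['sensitivity']:.3f}  "
      f"specificity {m['specificity']:.3f}  accuracy {m['accuracy']:.3f}")
print(f"artifacts (trace CSV, best model, metrics JSON) in "
      f"{result.output_dir}")
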
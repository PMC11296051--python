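"""Train both detectors on a small cohort and evaluate per-dive counts.

A deliberately small configuration (8 individuals, reduced window budgets)
so the whole example runs in about a minute; the package's reference
experiment in scripts/acceptance.py uses a larger cohort.
"""

import json

import pcedetect as p
from pcedetect.pipeline import RunConfig, prepare_cohort, run_experiment

cfg = RunConfig(
    sim=p.SimConfig(n_individuals=8, trip_duration_s=900, seed=3,
                    p_nonforager=0.0),
    sampler=p.SamplerConfig(epoch_windows_train=2000, epoch_windows_val=800,
                            split_tolerance=0.15),
    cnn=p.CnnConfig(epochs=5),
    vnet=p.VnetConfig(epochs=5),
    seed=3,
)

processed = prepare_cohort(p.simulate_cohort(cfg.sim), cfg)
result = run_experiment(processed, cfg, split_seed=3, model_seed=3)

for kind in ("cnn", "vnet"):
    reg = result.reports[kind].regression
    print(f"{kind}: slope={reg['slope']:.3f} intercept={reg['intercept']:.3f} "
          f"R^2={reg['r_squared']:.3f}")
print("split:", json.dumps(result.summary()["split"], indent=2))
# A slope near 1 with high R^2 means the detector recovers the number of
# captures per dive on individuals it has never seen.
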
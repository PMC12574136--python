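"""How event coverage and the r threshold shape accuracy.

Two desk-scale experiments: (i) held-out AUC along an event-coverage ladder
(emulating pooling reads across samples of the same cell type), and (ii)
macro accuracy as the supplied expected methylated fraction r sweeps around
the true fraction r*.
"""

from fragmeth import FragilityModel, SimulationConfig
from fragmeth.simulate import coverage_ladder, r_sweep

base = SimulationConfig(n_islands=200, mean_events_per_island=30, seed=0)
ladder = coverage_ladder(base, multipliers=(1, 5, 10, 20), seeds=range(3))
print("held-out AUC by event-coverage multiplier (median of 3 seeds):")
print(ladder.groupby("multiplier")["auc"].median().to_string(float_format="%.3f"))
print()

sweep_cfg = SimulationConfig(n_islands=200, mean_events_per_island=2000,
                             r_star=0.2, seed=5)
sweep = r_sweep(sweep_cfg, fragility=FragilityModel(meth_cpg_multiplier=2.0))
print("macro accuracy vs supplied r (true fraction r* = "
      f"{sweep['r_true'].iloc[0]:.2f}):")
print(sweep[["r", "macro_accuracy"]].to_string(index=False, float_format="%.3f"))
print()
print("AUC climbs steadily with coverage — more 5'-end events per island "
      "resolve the break spectrum better — and macro accuracy peaks when "
      "the supplied r matches the dataset's true methylated fraction.")
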
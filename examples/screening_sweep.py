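"""Rank candidate vesicle formulations by leakage half-time.

A Cartesian sweep over vesicle radius and surface mass-transfer
coefficient, ranked best (longest drug retention) first -- the
in-silico pre-filter that narrows a formulation space before any bench
work.
"""

from lipokin import SweepSpec, run_sweep

sweep = SweepSpec(
    grids={
        "mlv.radius_m": [0.5e-6, 1e-6, 2e-6],
        "mlv.kc_ms": [1e-8, 1e-7, 1e-6],
    },
    metrics=["leakage_half_time"],
    fixed={"mlv.diffusivity_m2s": 1e-13},
)

table = run_sweep(sweep)
print(table.to_string(
    index=False,
    formatters={"leakage_half_time": lambda v: f"{v:.4g}",
                "mlv.radius_m": lambda v: f"{v:.2g}",
                "mlv.kc_ms": lambda v: f"{v:.2g}"},
))

best = table.iloc[0]
print(f"\nbest retention: R = {best['mlv.radius_m']:.2g} m, "
      f"kC = {best['mlv.kc_ms']:.2g} m/s -> "
      f"half-time {best['leakage_half_time']:.4g} s")

# Large vesicles with a tight outer bilayer (small kC) hold their payload
# longest; the table quantifies by how much, turning two formulation
# levers into a single ranked screening readout.
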
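"""Load-and-fail: ligated fraction across substrate stiffness x myosin force.

A small grid (3 stiffnesses x 4 forces, 1 replicate, 150-s runs) with the
contractile load applied to every ligated integrin.  The full-resolution
version of this experiment is `adhesim sweep` with a YAML grid.
"""

from adhesim.sweeps import SweepSpec, pivot_heatmap, run_sweep

spec = SweepSpec(
    grid={"k_sub": [0.1, 0.4, 0.7], "F_myo": [0.0, 20.0, 35.0, 45.0]},
    n_reps=1,
    base_seed=7,
    base={"t_total": 150.0, "t_burnin": 75.0, "myo_scope": "global"},
    window=(75.0, 150.0),
)
table = run_sweep(spec)
hm = pivot_heatmap(table, value="mean_ligated_pct")
print("mean ligated % (rows: k pN/nm, columns: F_myo pN)")
print(hm.round(1).to_string())
print("\nAt each stiffness the ligated fraction rises with load toward the")
print("catch-slip optimum (~30 pN) and collapses deep in the slip regime;")
print("without load, stiffer substrates hold slightly more integrins bound.")
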
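"""Baseline condition: 300 integrins on a 0.6 pN/nm substrate, no fiber.

Runs 200 simulated seconds and prints the steady-state adhesion metrics
(averaged over 100-200 s, after the ligated count has plateaued).
"""

from adhesim import run, summarize, validate_params

params = validate_params({"seed": 1, "k_sub": 0.6, "t_total": 200.0})
traj = run(params)
s = summarize(traj)

print(f"mean ligated integrins : {s.mean_ligated_pct:5.1f} %  "
      "(fraction of the 300 receptors bound to a ligand at any instant)")
print(f"binding events         : {s.bind_rate:5.1f} /s  (domain-wide)")
print(f"unbinding              : {s.unbind_pct_per_s:5.1f} %/s of integrins")
print(f"mean total bound time  : {s.mean_total_ligated_time:5.1f} s per integrin "
      f"(of {params.t_total:.0f} s simulated)")
print(f"mean rupture tension   : {s.mean_rupture_tension:5.2f} pN  "
      "(thermal stretch only -- no myosin load here)")
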
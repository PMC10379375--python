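"""Generate a small synthetic TI panel study and look at one curve.

A study is a set of flavoring materials (essence / oil / flavor types),
replicate time-intensity curves per material and panelist, and one VAS
beany-intensity rating per material and panelist.
"""

from timask import SyntheticConfig, generate_study

cfg = SyntheticConfig(n_essence=3, n_oil=3, n_flavor=4,
                      n_panelists=5, n_replicates=4, seed=42)
study = generate_study(cfg)

print(f"materials: {len(study.materials)}   curves: {len(study.curves)}   "
      f"VAS ratings: {len(study.vas)}")

c = study.curves[0]
print(f"\nfirst curve: material={c.material_id} panelist={c.panelist_id} "
      f"replicate={c.replicate}")
print(f"  duration {c.times[-1]:.0f} s at 1 Hz, peak intensity "
      f"{c.intensities.max():.1f} a.u.")

truth = study.truth.set_index("material_id")
print("\nground-truth decay-phase areas (AreaDec) by type — the quantity the")
print("masking link is driven by; oils persist longest, essences vanish fast:")
print(truth.groupby("mtype")["AreaDec"].mean().round(0).to_string())
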
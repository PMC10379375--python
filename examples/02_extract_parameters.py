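"""From replicate curves to the 14 TI parameters of one material.

Replicates are smoothed, the three most intermediate ones are kept, the
survivors are averaged, and the average curve is segmented into increase /
plateau / decrease phases from which the 14 scalars are read.
"""

from timask import RunConfig, SyntheticConfig, extract_parameter_matrix, generate_study

study = generate_study(SyntheticConfig(n_essence=2, n_oil=2, n_flavor=2,
                                       n_panelists=5, n_replicates=4, seed=7))
matrix, phases = extract_parameter_matrix(study.curves, RunConfig())

print("phase boundaries (s) per material:")
print(phases.round(1).to_string(index=False))

print("\nselected TI parameters (a.u., s, a.u.*s):")
cols = ["Tstart", "Imax", "DurInc", "DurDec", "AreaInc", "AreaDec"]
print(matrix.data[cols].round(1).to_string())
print("\nDurInc/AreaInc describe how gradually the flavor builds;"
      "\nDurDec/AreaDec how long and how much it lingers after the peak.")
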
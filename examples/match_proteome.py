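"""Correlate theoretical masses with an experimental proteome mass list.

Uses the packaged 16-row transcriptome-vs-proteome table: theoretical
column against experimental column at two tolerances.
"""
from venomkit import ProteomeMass, load_table3, match_masses

t3 = load_table3()
theory = list(zip(t3["names"], t3["theor_mw_da"]))
experiment = [ProteomeMass(rt, mw) for rt, mw in zip(t3["rt_min"], t3["exp_mw_da"])]

for tol in (4.0, 1.0):
    report = match_masses(theory, experiment, tol=tol)
    print(f"tolerance ±{tol} Da: {report.n_exp_matched}/16 experimental masses matched")

# At ±4 Da all 16 components correlate (the published pairing allows up to
# 3.5 Da of deviation); at ±1 Da two loose pairs drop out, leaving 14.
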
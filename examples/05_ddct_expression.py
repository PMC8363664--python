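"""Relative gene expression from qPCR Ct values by 2^-ΔΔCt.

Simulates a Ct table in which CDKN1A (encoding the p21 CDK inhibitor) is
repressed four-fold by oncogene activation, then recovers the fold change:
ΔCt normalises each sample to the GAPDH reference, ΔΔCt to the untreated
calibrator samples, and expression = 2^-ΔΔCt.
"""

import ori_induce as oi

records, truth = oi.simulate_ct_table(
    target_genes=["CDKN1A"],
    conditions=["untreated", "gsk3i"],
    true_fold_changes={"CDKN1A": {"untreated": 1.0, "gsk3i": 0.25}},
    calibrator_condition="untreated",
    n_replicates=5, noise_sd_ct=0.15, seed=11)

df = oi.ddct_expression(records, "CDKN1A")
print(df.round(3).to_string(index=False))

drug = df[df["sample_id"].str.startswith("gsk3i")]["expression"]
print(f"\nmean CDKN1A expression after GSK3 inhibition: {drug.mean():.3f}")
print("(planted fold change: 0.25 — i.e. 4-fold repression relative to the")
print(" untreated calibrator; calibrator samples centre on 1 by definition)")
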
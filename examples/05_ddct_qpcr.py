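"""Relative qPCR quantification with the 2^-ddCt method.

Fold difference of a target between two conditions, each normalized to a
reference gene measured in the same sample.
"""

from mirtail.modstats import ddct_fold_change

# Ct values: target and reference in condition B (knockdown) and A (control)
ct_target_b, ct_ref_b = 22.0, 15.0
ct_target_a, ct_ref_a = 20.0, 15.0

fold = ddct_fold_change(ct_target_b, ct_ref_b, ct_target_a, ct_ref_a)
print(f"dCt(B) = {ct_target_b - ct_ref_b:.1f}, dCt(A) = {ct_target_a - ct_ref_a:.1f}")
print(f"fold change (B vs A) = 2^-ddCt = {fold:.2f}")
print("a value of 0.25 means the target needs two more PCR cycles in B: 4x less RNA")
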
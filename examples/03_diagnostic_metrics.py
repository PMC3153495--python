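"""Diagnostic accuracy from a 2x2 table, in both rounding conventions.

The table below is a 143-patient comparison of IHC calls against
sequencing truth for L858R: 38 true positives, 23 false positives,
5 false negatives, 77 true negatives.
"""

from stainclass import ConfusionTable, diagnostic_metrics

table = ConfusionTable(tp=38, fp=23, fn=5, tn=77)

for mode in ("exact", "printed"):
    m = diagnostic_metrics(table, rounding=mode)
    print(f"{mode}:")
    print(f"  sensitivity {m.sensitivity:.4f}%  specificity {m.specificity:.4f}%")
    print(f"  PPV {m.ppv:.4f}%  NPV {m.npv:.4f}%  accuracy {m.accuracy:.4f}%")
    print(f"  LR+ {m.lr_plus:.4f}  LR- {m.lr_minus:.4f}")

# 'printed' rounds the operating point to one decimal percent before forming
# the likelihood ratios, giving LR+ = 88.4/23.0 = 3.843; exact arithmetic
# gives 3.842 -- diagnostic tables in the literature typically use the former.
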
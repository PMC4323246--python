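"""Exact statistics for tricellular-contact (TC) localization counts.

Compares the mutant clone's accumulation proportion against wild type with
the log-space exact test; the association is so strong that p-values around
1e-70 still carry full precision.
"""

from exomefunnel.tcstats import compare_conditions

# (clone label, TCs with tagged-protein accumulation, TCs examined)
flag_counts = [("WT", 593, 618), ("P69H", 411, 722)]
tricellulin_counts = [("WT", 573, 618), ("P69H", 360, 722)]

for title, counts in (("FLAG (angulin-2/ILDR1)", flag_counts),
                      ("tricellulin recruitment", tricellulin_counts)):
    df = compare_conditions(counts, reference_label="WT")
    print(f"--- {title} ---")
    print(df.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
    print()

print("The mutant protein reaches only ~57% of TCs (wild type ~96%) and")
print("recruits tricellulin to ~50% (wild type ~93%): a partial, not total,")
print("loss of tricellular localization; log10_p numbers the exact-test")
print("evidence against equal proportions.")
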
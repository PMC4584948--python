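"""Classify endosperm expression trajectories into temporal pattern classes.

The four non-flat classes describe trajectories over the consecutive 7-,
10- and 15-DAP endosperm stages; steps are called at a 1.5-fold change.
"""

from endomir.patterns import classify_temporal_pattern, endosperm_enrichment

profiles = {
    "falls then stays":   (820, 140, 150),
    "rises throughout":   (40, 90, 400),
    "peaks at 10 DAP":    (30, 300, 45),
    "trough at 10 DAP":   (260, 35, 280),
    "barely moves":       (100, 104, 96),
}
for label, values in profiles.items():
    call = classify_temporal_pattern(values)
    print(f"{label:18s} {values} -> {call.pattern:18s} "
          f"(steps x{call.fold_7_10:.2f}, x{call.fold_10_15:.2f})")

# Endosperm/kernel enrichment: the ratio of tissue means.
enr = endosperm_enrichment(kernel_mean=2.0, endosperm_mean=820.0, eps=0.0)
print(f"\nendosperm vs kernel enrichment: {enr.fold:.1f}-fold")
# A fold of 410 means the miRNA averages 410x higher RPM in endosperm.
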
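"""Simulate one full cytotoxicity assay plate and print both readouts.

The plate mirrors the standard design: target cells loaded with calcein,
NK effectors at E:T ratios 2:1, 1:1 and 0.5:1 in triplicate, plus six
spontaneous-release (plain media) and six maximum-release (detergent)
control wells. Every well is simulated, imaged, detected and gated, and
percent specific lysis is computed by the supernatant-release formula and
by the live-cell-count formula.
"""

from calcytox import PlateConfig, run_plate

config = PlateConfig(master_seed=7)
result = run_plate(config)

print(f"cell line        : {config.cell_line_label}")
print(f"targets per well : {config.n_targets_per_well}")
print(f"gate             : integrated intensity >= "
      f"{result.gate.min_integrated_intensity:.0f} counts "
      f"(q={result.gate.percentile_q:g} of spontaneous)")
print(f"spontaneous release: {result.spont_pct_of_max:.1f}% of maximum "
      f"-> dynamic range {result.dynamic_range_pct:.1f}%")
print()
print(result.summary.round(2).to_string(index=False))
print()
print("The count-based (image cytometry) percent lysis exceeds the "
      "release-based value at every E:T ratio: killed targets retain part "
      "of their calcein (entirely, for apoptotic bodies), which suppresses "
      "the supernatant signal but not the loss of bright live cells.")
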
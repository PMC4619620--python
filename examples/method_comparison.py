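"""Paired comparison of the two readouts across a simulated donor panel.

Five donors (varying NK potency) each run a triplicate assay at E:T 1:1;
the 15 (release %, imaging %) pairs are compared with the Wilcoxon
matched-pairs signed-rank test, exactly as wet-lab method comparisons are
analyzed.
"""

from calcytox import PlateConfig, compare_methods, run_donor_panel

config = PlateConfig(n_targets_per_well=4_000, n_control_replicates=3,
                     master_seed=0)
pairs = run_donor_panel(config, n_donors=5, et_ratio=1.0, seed=42)
print(pairs.round(2).to_string(index=False))

cmp = compare_methods(pairs["pct_lysis_release"], pairs["pct_lysis_imaging"])
print()
print(f"median release % lysis : {cmp.median_release:6.2f}")
print(f"median imaging % lysis : {cmp.median_imaging:6.2f}")
print(f"Wilcoxon W = {cmp.statistic:g}, two-tailed p = {cmp.p_value:.3g} "
      f"({cmp.n_pairs} pairs)")
print()
print("A significant p with a higher imaging median reproduces the "
      "headline effect: counting bright live cells reports more specific "
      "lysis than measuring released calcein, because retained calcein "
      "never reaches the supernatant.")
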
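"""Per-mode statistical comparison of left vs right femur shape.

All femurs (rights mirrored) enter one 65-point model; Welch's t-test per
mode asks whether left and right populations differ in mean shape, with
Bonferroni correction over the retained modes.
"""

from femsym import SyntheticConfig, analyze_symmetry, generate_dataset

contours, _ = generate_dataset(SyntheticConfig(n_subjects=100, seed=1))
report = analyze_symmetry(contours)

print(f"{report.n_subjects} subjects, {report.retained_modes} retained modes")
print(f"mean left-right point-to-curve distance: {report.mean_lr_distance:.2f} mm")
print(f"Bonferroni per-mode threshold: {report.bonferroni_alpha:.4f}")

cols = ["mode_index", "mean_b_left", "mean_b_right", "welch_t", "p_value",
        "significant_raw", "significant_bonferroni"]
print(report.round_for_reporting()[cols].head(8).to_string(index=False))
n_raw = int(report.per_mode["significant_raw"].sum())
n_bonf = int(report.per_mode["significant_bonferroni"].sum())
print(f"{n_raw} modes significant at alpha=0.05 raw, {n_bonf} after Bonferroni")
# Under the generator's exchangeable construction no true left-right shape
# difference exists, so significant modes here are false positives at the
# expected rate.
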
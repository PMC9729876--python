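"""Differential-expression screening and top-marker selection.

Runs the Welch-t screen on a synthetic cohort, applies the DEG filter
(|log2FC| > 1 and p < 0.01) and selects the top two up- and down-regulated
miRNAs — the four inputs of the diagnostic circuit.  Also picks K-means
representative cases, the samples one would validate individually.
"""

from mirdsd import compute_de, filter_degs, generate_cohort, representative_cases, select_top_markers
from mirdsd.scenarios import diagnostic_marker_cohort

spec, _ = diagnostic_marker_cohort(seed=0)
expr, clinical = generate_cohort(spec)

de = compute_de(expr, clinical)
degs = filter_degs(de, logfc_threshold=1.0, p_threshold=0.01)
print(f"{len(degs)} of {len(de)} genes pass |log2FC| > 1 and p < 0.01")
print(degs.sort_values("log2FC", ascending=False).to_string(index=False, float_format="%.3g"))

panel = select_top_markers(degs, n_up=2, n_down=2)
print("\nbiomarker panel (tumor channel):", [f"{g} ({fc:+.2f})" for g, fc in panel.positive])
print("biomarker panel (health channel):", [f"{g} ({fc:+.2f})" for g, fc in panel.negative])

reps = representative_cases(expr, clinical, k=10, seed=0)
print(f"\nK-means (K=10) representatives: {len(reps['tumor'])} tumor, {len(reps['normal'])} normal")
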
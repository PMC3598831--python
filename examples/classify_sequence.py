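"""Thin-tail and fluffy-tail tests on one synthetic enhancer-like sequence.

Builds a 1200-base sequence carrying six planted motif families (10 mutated
copies each), runs both tests with r=50 composition-preserving shuffles, and
prints the coefficients next to those of a matched i.i.d. background.
"""

import thintail as tt

motifs = ("GATTAG", "CACGTG", "TTACGC", "AGGCTA", "CCGATT", "TGCGAA")
crm_spec = tt.SyntheticSpec(length=1200, motifs=tuple(m[:5] for m in motifs),
                            copies=10, mutation_rate=0.15, seed=42)
crm = tt.generate_crm_like(crm_spec)
bg = tt.generate_background(tt.SyntheticSpec(length=1200, seed=43))

for name, rec in [("planted-cluster sequence", crm), ("i.i.d. background", bg)]:
    analysis, _ = tt.analyze_sequence(rec, r=50, rng=7, which="both")
    print(f"{name} ({rec.id}, L={analysis.L}, M={analysis.M} seed-words)")
    print(f"  kurtosis k0 = {analysis.k0:+.3f}   (0 would be a normal-shaped Z distribution)")
    print(f"  E  = {analysis.E_coef:.3f}  (first thinness coefficient; <0.6 points to CRM)")
    print(f"  T  = {analysis.T_coef:+.3f}  (kurtosis vs {analysis.r} shuffles; <0 points to CRM)")
    print(f"  F  = {analysis.F_coef:+.3f}  (fluffy-tail baseline; >2 points to CRM)")
    print(f"  labels: E -> {analysis.label_E}, T -> {analysis.label_T}, "
          f"combined -> {analysis.label_combined}, F -> {analysis.label_F}\n")

print("Planted clusters inflate the largest similar-word family, so F separates the")
print("two sequences sharply; they also fatten the Z-score tail, which RAISES the")
print("kurtosis-based E and T relative to background (see docs/methods.md on why the")
print("thin-tail direction reported for real regulatory regions needs sequence")
print("features, like repeats in the negative class, that this generator omits).")
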
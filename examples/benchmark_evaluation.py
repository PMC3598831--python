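"""A small labeled benchmark end to end: simulate, test, score.

Generates 15 CRM-like + 15 background records, runs both tests (r=20 shuffles
to keep this example quick), and prints the sensitivity/specificity/accuracy
of each coefficient against the ground truth.
"""

import pandas as pd

import thintail as tt
from thintail.cli import evaluate, results_to_frame
from thintail.pipeline import analyze_records

records, truth = tt.generate_benchmark(15, 15, rng_seed=1)
analyses = analyze_records(records, rng=2, r=20, which="both")
results = results_to_frame(analyses)
truth_df = pd.DataFrame(truth, columns=["id", "label"])

print(f"{len(records)} records analyzed (r=20 shuffles each)\n")
print(f"{'rule':>9} {'SN':>7} {'SP':>7} {'accuracy':>9}")
for which in ("E", "T", "F", "combined"):
    s = evaluate(results, truth_df, which=which)
    print(f"{which:>9} {100 * s.sensitivity:6.1f}% {100 * s.specificity:6.1f}% {100 * s.accuracy:8.1f}%")

print("\nSN = fraction of planted-cluster records called CRM; SP = fraction of")
print("backgrounds called NCNR. On this synthetic benchmark the fluffy-tail F")
print("is the informative direction; E and T respond to planted clusters by")
print("rising (fat tails), the opposite of the thin-tail signature seen in")
print("real regulatory sequence corpora.")
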
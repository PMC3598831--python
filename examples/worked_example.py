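"""Seed-words, similar-word sets and Z-scores on a 12-base toy sequence.

Scans ACGACGCCGACT with word length m=5 and up to j=1 substitution,
printing every seed-word's family occurrence count n, its expectation and
variance under the sequence's own Bernoulli composition, and the resulting
overrepresentation Z-score.
"""

import thintail as tt

rec = tt.SequenceRecord(id="toy", seq="ACGACGCCGACT")
idx = tt.enumerate_seed_words(rec, 5)
print(f"sequence {rec.seq} (L={rec.length}) has M={idx.M} distinct 5-letter seed-words\n")

prof = tt.z_profile(rec, m=5, j=1)
print(f"{'seed':>6} {'n':>3} {'E':>7} {'V':>7} {'Z':>7}")
for seed, n, E, V, Z in zip(prof.seeds, prof.n, prof.expectation, prof.variance, prof.z):
    print(f"{seed:>6} {n:>3d} {E:>7.3f} {V:>7.3f} {Z:>7.2f}")

ws = tt.hamming_ball("ACGAC", 1)
print(f"\nThe similar-word set of ACGAC holds {len(ws.members)} words within 1 mismatch;")
print(f"{tt.count_set_occurrences(rec, ws)} of the sequence's windows belong to it "
      "(ACGAC, ACGCC and CCGAC each occur once).")
print("A large positive Z would mean the family occurs far more often than a "
      "composition-matched random sequence predicts.")
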
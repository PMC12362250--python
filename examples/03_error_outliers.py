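"""Tukey's-fences outlier calling on per-position error scores.

Modified bases distort basecalling, so a per-position error score computed
between two samples flags them.  This example uses the package's internal
fallback error score (arcsine-stabilized error-rate difference between two
simulated samples, one with an inflated-error site); an external error
profiler's TSV can be ingested the same way via load_error_table.
"""

import numpy as np

import trnamod as tm
from trnamod.erroutlier import call_outliers, fallback_error_scores, outlier_frame

refs = tm.ReferenceSet([tm.simulate_references(1, seed=301).entries[0]])
ref = refs.entries[0]
target = ref.body_len // 2

reads_a, _ = tm.simulate_reads(refs, per_ref_depth=80, truncation_prob=0.0, seed=302)
reads_b, _ = tm.simulate_reads(refs, per_ref_depth=80, truncation_prob=0.0, seed=303)
alns_a = tm.filter_alignments(tm.align_all(reads_a, refs))
alns_b = tm.filter_alignments(tm.align_all(reads_b, refs))

# inject systematic miscalls at the target site in sample b
rng = np.random.default_rng(304)
full_idx = ref.body_to_full(target)
for aln in alns_b:
    for i, (rp, fp, op) in enumerate(aln.pairs):
        if fp == full_idx and op == "=" and rng.random() < 0.5:
            aln.pairs[i] = (rp, fp, "X")

table = fallback_error_scores(alns_a, alns_b, refs)
calls = call_outliers(table, k=1.5, score_floor=10.0)
df = outlier_frame(calls)

print(df[df["reported"]].to_string(index=False, float_format=lambda x: f"{x:.2f}"))
print(f"\ntruth: errors were injected at body position {target}.")
print("a position is reported when score > Q3 + 1.5*IQR and score >= 10.")
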
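"""Off-label modification detection by symmetric KL divergence.

A wild-type sample carries a 'non-pseudouridine' uridine modification whose
prediction scores fall in the mid-range (the caller was not trained for
it); the knockout lacks it.  Comparing the smoothed per-site score
histograms between the samples makes the site stand out even though neither
sample would call it with the on-label fraction statistic.
"""

import trnamod as tm
from trnamod.klcompare import kl_frame
from trnamod.simulate import ABNORMAL_DIST

refs = tm.simulate_references(1, seed=201)
ref = refs.entries[0]
u_sites = [p for p in range(1, ref.body_len + 1) if ref.body_base(p) == "T"]
target = u_sites[len(u_sites) // 2]
models = {(ref.ref_id, target): tm.SiteModel(target, 0.7, modified_dist=ABNORMAL_DIST)}

wt = tm.simulate_site_table(refs, models, n_reads=400, seed=202)
ko = tm.simulate_site_table(refs, {}, n_reads=400, seed=203)

records = tm.compare_samples(wt, ko, min_coverage=100)
df = kl_frame([r for r in records if r.passed_coverage])
df["sym_kl_norm"] = tm.min_max_normalize(df["sym_kl"].tolist())
top = df.sort_values("sym_kl", ascending=False).head(5)

print(top.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print(f"\ntruth: the modified site is body position {target}.")
print("sym_kl = D(P||Q) + D(Q||P) in nats over 10-bin smoothed score histograms;")
print("the modified site's divergence dwarfs the background of unmodified uridines.")
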
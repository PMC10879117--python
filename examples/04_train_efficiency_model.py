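"""Train the per-position efficiency network with endogenous channels.

Encodes each site as a 40 x (4 + k) matrix (one-hot sequence plus
factor channels), runs the shuffled stratified 80/20 protocol, and
compares the sequence-only model against the factor-aware one: on data
where factors truly modulate editing, the endo model should test
better.
"""

import numpy as np

from bescope import RunConfig, simulate_dataset, summarize_site
from bescope.efficiency import DEFAULT_ENDO_CHANNELS, TrainingProtocol, build_dataset, train

ds = simulate_dataset(n_sites=600, editor="CBE", depth=5_000, replicates=1, seed=4)
cfg = RunConfig(editor="CBE")
summaries = [summarize_site(ds.tables[s.site_id][0], s, cfg) for s in ds.sites]
protocol = TrainingProtocol(n_shuffles=3, seed=4)
strata = np.array([
    int(any(v for k, v in ds.annotations[s.site_id].binary.items()
            if not k.startswith("methylation_pos")))
    for s in ds.sites
])

results = {}
for label, channels in [("seq", ()), ("endo", DEFAULT_ENDO_CHANNELS["CBE"])]:
    x, y, mask = build_dataset(ds.sites, summaries, ds.annotations, channels)
    res = train(x, y, mask, "CBE", channels=channels, strata=strata,
                protocol=protocol)
    results[label] = res
    per_shuffle = ", ".join(f"{s.test_r:.3f}" for s in res.shuffles)
    print(f"{label:>4} model ({4 + len(channels)} channels): "
          f"pooled test R = {res.pooled_test_r:.3f}  [shuffles: {per_shuffle}]")

gain = results["endo"].pooled_test_r - results["seq"].pooled_test_r
print(f"\nendogenous channels add {gain:+.3f} pooled test R on this dataset,")
print("because the generator couples editing to expression, chromatin and")
print("methylation state; on factor-free data the two models coincide.")
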
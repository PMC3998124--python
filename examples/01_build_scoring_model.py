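"""Build an Ri scoring model from aligned binding sites and score probes.

The model turns per-position base frequencies into weights of
2 + log2 f(b, l) bits; a site's score is the sum of its weights, and the
collection itself fixes the operating threshold at mean − 1.5·SD.
"""

from metaregulon import SiteCollection, build_scoring_model, rsequence, score_sequence

sites = SiteCollection.from_sequences(
    ["GAACGTTC", "GTACGTTC", "GAACGTAC", "CAACGTTC", "GAACGATC", "TAACGTTG"]
)
model = build_scoring_model(sites, pseudocount=0.25)

print(f"motif width:        {model.width} bp")
print(f"information (bits): {rsequence(model):.3f}")
print(f"collection mean:    {model.mean:.3f} bits")
print(f"collection SD:      {model.sd:.3f} bits")
print(f"scan threshold:     {model.threshold:.3f} bits  (mean - 1.5 SD)")
for probe in ("GAACGTTC", "CTACGATG", "TTTTTTTT"):
    print(f"score({probe}) = {score_sequence(model, probe):8.3f} bits")

# The consensus-like probe scores near the collection mean; the scrambled
# probe scores far below the threshold and would never be reported.
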
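"""Classify COGs as prototypical regulon members from their score spectra.

Sites of genuinely regulated genes score approximately normally around
the motif information content (~16 bits), so the cumulative count of
sites above t is nearly linear in t over 12-20 bits.  The classifier
requires R^2 > 0.85, one site above 16 bits and >= 10 sites in range.
"""

import numpy as np

from metaregulon import ClassifierConfig, make_profile

rng = np.random.default_rng(1)
cfg = ClassifierConfig()

cases = {
    "regulated_cog": rng.normal(16.2, 2.9, size=30),     # true regulon member
    "sparse_cog": rng.normal(16.2, 2.9, size=6),         # too few sites
    "background_cog": rng.uniform(8.5, 13.5, size=40),   # chance hits only
}

print(f"{'COG':>15s} {'n':>4s} {'in12-20':>8s} {'max':>6s} {'R2':>6s}  call")
for name, scores in cases.items():
    p = make_profile(name, scores.tolist(), cfg)
    call = "PROTOTYPICAL" if p.prototypical else "-"
    print(
        f"{name:>15s} {len(p.scores):>4d} {p.n_in_range:>8d} "
        f"{p.max_score:>6.1f} {p.r2:>6.3f}  {call}"
    )
# Only the well-populated, high-scoring, linear spectrum passes all
# three clauses of the rule.
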
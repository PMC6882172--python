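"""The random-rank null model for the first interface pair.

For a dimer with N candidate residue pairs of which M are interface pairs,
draw 1000 pairs at random (without replacement) and record the position of
the first interface pair (1000 if none is drawn).  The expectation of this
rank is the bar a predictor's RFPP has to beat.  Computed two independent
ways — closed form and Monte-Carlo simulation of the draws — for the
largest test-set dimer (PDB 1BKD: N = 321,630, M = 687).
"""

import ppilstm as pl

spec = pl.BaselineSpec(N=321_630, M=687, draws=1000, reps=10 ** 6, seed=0)

exact = pl.expected_rfpp(spec)
mc = pl.simulate_rfpp_mc(spec)

print(f"N = {spec.N:,} candidate pairs, M = {spec.M} interface pairs, "
      f"{spec.draws} draws")
print(f"closed-form  E[min(X, {spec.cap})] = {exact:.2f}")
print(f"Monte Carlo ({spec.reps:,} reps)   = {mc.estimate:.2f} "
      f"+/- {mc.standard_error:.2f}")
print("(a ranking model with RFPP 73 on this dimer beats random by ~6x;"
      " random needs ~413 guesses on average before hitting an interface pair)")
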
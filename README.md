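# hgtnet

Inference of horizontal gene transfer (HGT) networks between bacterial taxa
from the length distribution of maximal exact sequence matches.

## The problem

Very long exact matches (≥ 1 kb) between genomes of *different* genera are
fingerprints of recent horizontal transfer: point mutations destroy perfect
identity far too quickly for such segments to survive vertical descent.
`hgtnet` turns the *whole distribution* of match lengths — not just their
presence — into a quantitative probe of the gene-exchange network: who
trades DNA with whom, how fast, and whether exchange is direct or routed
through unobserved intermediate "hub" taxa.  It is aimed at comparative
genomicists studying gene flow in bacterial families (e.g. the
*Enterobacteriaceae*) and at modellers who need a generative simulator of
sequence-level HGT.

## The model

A transferred segment shared by a set *s* of *n* taxa sits at the leaves of
a dissemination tree of total length τ (units of the mutation rate, μ = 1).
A single event gives an exponential match-length distribution (MLD)

    m(r | τ) = L τ² e^(−τ r),

and a continuous transfer process with tree-length density P_s(τ) gives
m_s(r) = L·P̃_s″(r), the second derivative of its Laplace transform.  On a
network where taxon *i* has transferability γ_i and pairwise per-bp rate
ρ_ij = γ_i γ_j (symmetric, rank-1), the large-r MLD is a sum of two power
laws:

    m_s(r) =  L_d (n−2)! S(ρ, s) / r^(n+1)   (direct, within-set)
            + 2 L_h ∏_i ρ_0i / (n(n+1) r^(n+2))   (via an unobserved hub),

so the observed log–log slope −(n+1) vs −(n+2) identifies the dominant
pathway.  A model with n + 3 parameters (γ_1..γ_n, γ_0, the effective
mobilome sizes L_d and L_h) is fitted jointly to all 2ⁿ − n − 1 MLDs by a
15%-trimmed mean squared log-difference objective (seeded differential
evolution + L-BFGS-B).  Tail exponents are estimated by the method of
moments, α̂ = (2m − 1)/(m − 1) with m = mean/(r_min − ½); episodic MLDs are
fitted by small exponential mixtures with closed-form crossovers.

A forward Gillespie simulator (element-wise transfer, per-base mutation)
doubles as the brute-force oracle for all of the above and as the test
fixture generator.

## Worked example

Simulate two taxa exchanging 5 kb mobile elements at symmetric per-bp rate
ρ = 0.15 (in mutation-rate units), pool matches ≥ 25 bp over seeded
replicates, and estimate the tail exponent:

```python
import numpy as np
from hgtnet import (TaxonNetwork, SimConfig, pooled_match_lengths,
                    estimate_alpha_moments)

net = TaxonNetwork(taxa=("A", "B"),
                   rate_matrix=np.array([[0, 0.15], [0.15, 0]]),
                   L_direct=1e5)
cfg = SimConfig(network=net, L=100_000, L_e=5_000, T=1.0,
                seed=7, min_len=25, replicates=100)
lengths = pooled_match_lengths(cfg, [("A", "B")])[("A", "B")]
print(len(lengths), "matches")
print("alpha =", round(estimate_alpha_moments(lengths, 25), 3))
```

```
2192 matches
alpha = 3.059
```

The estimate lands at the theoretical pairwise exponent α = n + 1 = 3 (the
exact finite-rate expectation for these settings is 2.97): pairwise
exchange is direct-transfer dominated.  A trio whose members communicate
only through an unobserved hub instead yields α ≈ n + 2 = 5.

The same pipeline is scriptable from the shell:

```sh
hgtnet simulate --config sim.json --seed 7 --replicates 100 --out-dir run/
hgtnet estimate-alpha --matches run/matches_A_B.tsv --r-min 25
hgtnet predict --network net.json --set A,B,C --r 1000:100000 --out curve.tsv
hgtnet fit --mlds mlds/ --taxa A,B,C,D --trim 0.15 --seed 1 --out fit.json
```

Every run writes a `.manifest.json` (command, parameters, seed, version);
re-running a manifest reproduces outputs byte-identically.

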
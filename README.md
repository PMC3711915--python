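# ringkmc

Stochastic kinetics of hexameric ring-ATPase assembly and subunit
poisoning.

Many AAA ATPases (spastin, katanin, ClpX, PAN, ...) are only active as
homo-hexameric rings that assemble reversibly from monomers. Two
experimental fingerprints of such enzymes are notoriously hard to
interpret: the apparent turnover rate k_obs rises with total enzyme
concentration (because assembly is concentration-driven), and
catalytically dead mutant subunits suppress wild-type activity by
co-assembling into mixed rings (the dominant-negative effect). Both
effects entangle assembly kinetics with intra-ring allosteric coupling.

`ringkmc` disentangles them by explicit simulation. It enumerates every
mixed wild-type (W) / mutant (M) assembly intermediate, generates the full
reaction network of a chosen assembly pathway, runs an exact Gillespie
(kinetic Monte Carlo) simulation of it, and provides the analysis models
used to fit titration curves. It is aimed at enzymologists who want to
test which allosteric coupling rule is consistent with their mutant-doping
data before committing to a mechanistic interpretation.

## The model

**Ring combinatorics.** Linear intermediates of n subunits have 2^n
distinct arrangements (left and right ends differ), so there are 4 dimers,
8 trimers and 16 tetramers. Closed hexamers are identified up to rotation
only — the ring has distinct upper and lower faces, so mirror images are
not merged — leaving 14 configurations: one per mutant count 0, 1, 5, 6,
three with two mutants (adjacent, one-gap, opposite), four with three and
three with four.

**Assembly pathways.** Hexamers form via 1–2–3–6 (dimer → trimer →
trimer+trimer closure), 1–2–4–6 (dimer → tetramer → tetramer+dimer
closure) or strictly sequential 1–2–3–4–5–6 monomer addition. Every step
is reversible; both attachment orientations are enumerated; reactions
that create the same subunit interface (W–W, W–M, M–W, M–M) share a rate
constant. On the 1–2–3–6 pathway this yields 16 forward trimerization and
64 forward ring-closure channels; on 1–2–4–6, 16 tetramerizations and 128
closures.

**Catalysis and allostery.** Only hexamers hydrolyze ATP. A wild-type
subunit runs at k_cat,WW unless a mutant in the same ring inhibits it
down to the basal k_cat,WM, according to an inhibition scheme:

| scheme | rule | offsets |
|---|---|---|
| 1, full-ring | any mutant silences the whole ring (MWC-like) | all |
| 2, both neighbours | a mutant inhibits its two direct neighbours | {+1, −1} |
| 3, oriented neighbour | a mutant inhibits one oriented neighbour | {+1} |
| none | mutants are allosterically neutral | {} |
| threshold(t) | ≥ t mutants per ring force all W basal | — |

Arbitrary interaction maps (e.g. a mutant acting on the second-next
subunit only, or two mutant alleles with different reach) are supported
through per-label offset sets. The catalytic channel of a ring with
n_fast fast and n_basal basal wild-type subunits fires at
(n_fast·k_cat,WW + n_basal·k_cat,WM)/n_W per hexamer, releases n_W ADP
and dissolves the ring into monomers, so each configuration's expected
ADP production equals its term in the census-weighted apparent turnover

    k_obs = Σ_configs count · (n_fast·k_cat,WW + n_basal·k_cat,WM) / n_Wt,total .

**Observables.** k_obs is measured from a linear fit of the ADP trace
after burn-in, per wild-type subunit. Titration curves can be fitted with
Michaelis–Menten, a binomial ring-mixture model (with incorporation
factor d), generalized non-competitive inhibition
(S/(Km+S))·(k_cat,WW·Ki + k_cat,WM·I)/(Ki+I), an empirical exponential,
and compared against a pseudo-first-order chain prediction.

## Worked example

```python
from ringkmc import (InhibitionScheme, SimulationConfig, run,
                     kobs_from_trace, kobs_mixed)
from ringkmc.ssa import steady_state_window, hexamer_census

cfg = SimulationConfig(n_Wt=1000, n_Mut=1000, seed=1,
                       scheme=InhibitionScheme.scheme2())
trace = run(cfg)                      # 100,000 Gillespie events
w = steady_state_window(trace)        # discard burn-in, check stationarity
print(kobs_from_trace(trace, window=w))
census = hexamer_census(trace, w)     # time-averaged ring counts by config
print(kobs_mixed(census, cfg.scheme, 5.0, 0.05, 1000))
```

prints

```
0.271
0.272
```

With 1000 mutants per 1000 wild-type subunits under both-neighbour
inhibition, the apparent turnover drops from the pure-wild-type 1.81 s⁻¹
(same seed, no mutant) to 0.271 s⁻¹ per wild-type subunit — and the ADP
slope agrees with the census-weighted prediction from the ring
composition (0.272 s⁻¹), confirming that the inhibition is fully
accounted for by who sits next to whom in the assembled rings. The most
populated mixed ring here is the alternating configuration (config 9,
~52 rings on time average), which scheme 2 silences completely.

The same experiment from the shell:

```sh
ringkmc enumerate --scheme 2                      # activity table as TSV
ringkmc simulate --n-wt 1000 --n-mut 1000 --seed 1 --out trace.csv
ringkmc sweep --variable n_Mut --grid 0,250,1000,4000 --n-wt 1000 --out sweep.csv
ringkmc fit --model noncompetitive --fix kcat_WW=5 --fix S=1000 --in curve.csv
```

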
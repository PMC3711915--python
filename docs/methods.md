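# Methods

## Model

The simulator treats a well-mixed, arbitrary unit volume containing
`n_Wt` wild-type (W) and `n_Mut` catalytically dead mutant (M) subunits,
initially all monomeric. Particles encounter each other without diffusion
limitation; ATP is saturating and not modelled explicitly. Assembly
proceeds along one of three pathways (1–2–3–6, 1–2–4–6, sequential
1–2–3–4–5–6); every assembly step is reversible, and only complete
hexameric rings are catalytically active.

Linear intermediates are ordered and carry no symmetry (2^n arrangements
of n subunits); rings are rotation-equivalence classes (14 for hexamers),
with reflections kept distinct because the ring has an upper and a lower
face. The canonical representative of a ring is its lexicographically
minimal rotation with the mutant letter sorting first; configurations are
numbered 1–14 by ascending mutant count, then ascending canonical
sequence. This numbering puts the adjacent / one-gap / opposite two-mutant
rings at positions 3/4/5 and the alternating ring at 9. The two
three-mutant rings 7/8 and the two four-mutant rings 11/12 have identical
activity patterns under every named scheme, so their relative order is a
neutral convention.

### Reaction generation and rate keying

Bimolecular joins are enumerated over ordered reactant pairs, and when
the partners differ in size both attachment orientations (left/right) are
generated as separate channels. This bookkeeping counts 4 dimerizations,
16 trimerizations and 64 ring closures on the 1–2–3–6 pathway, and 16
tetramerizations and 128 closures on 1–2–4–6; orientation channels that
happen to produce the same canonical ring remain distinct channels, and
their duplication is absorbed by the rate calibration below. Rates are
keyed by the newly formed interface (the ordered pair of subunit kinds in
the new contact); a ring closure forms two interfaces and uses the
wild-type rate only if both are W–W, otherwise the mutant-interface
class. Every forward channel has a reverse channel keyed by the broken
interface(s); for hexamers the reverse channels realize exactly the
distinct opposite-interface splits of each necklace (three trimer+trimer
axes, six tetramer+dimer axes, merged where rotational symmetry makes
them indistinguishable). `koff_mut_multiplier` scales every reverse rate
whose broken interface involves a mutant (100 for weakly bound mutants, 0
to lock mutants in until the ring turns over).

### Catalysis, ADP accounting and the two-level activity model

An inhibition scheme assigns each wild-type subunit in a ring to the fast
(k_cat,WW) or basal (k_cat,WM) class: a subunit is basal iff some mutant's
oriented offset set covers its position. Full-ring inhibition uses all
offsets, both-neighbour {+1, −1}, oriented-neighbour {+1}; the activity
table is invariant to the chosen ring direction (verified by test). The
threshold variant forces all wild-type subunits basal once the ring holds
at least t mutants — still a two-level model; fully inactivating variants
are expressed by setting k_cat,WM = 0. Generalized interaction maps
assign offset sets per mutant label, which covers proposals such as a
mutant acting only on its oriented second-next neighbour while a second
mutant allele is neutral.

The catalytic channel of a ring with n_W wild-type subunits fires at
(n_fast·k_cat,WW + n_basal·k_cat,WM)/n_W per hexamer, releases n_W ADP
and returns the subunits to the monomer pool. This convention makes each
configuration's expected ADP rate equal its census-weighted turnover term
while a pure wild-type ring fires at k_cat,WW per hexamer. An admissible
alternative — one ADP per subunit-level event with ring survival —
changes the decomposition flux of hexamers but not the expected ADP rate;
it is not implemented.

### Stochastic engine

The direct-method Gillespie algorithm draws waiting times from the total
propensity and channels proportionally to theirs, with the particle-number
conventions a = k·nA·nB (distinct reactants), a = (k/2)·nA·(nA−1)
(identical) and a = k·n (unimolecular). The mass-action ODE of the same
network uses k·xA·xB and (k/2)·xA², which makes the deterministic system
the exact large-number limit of the stochastic one — the basis of the
mean-field oracle test. The inner loop is compiled with numba; all random
numbers are pre-drawn from a seeded NumPy PCG64 generator, so a
(configuration, seed) pair reproduces a trace bit for bit. A total
propensity of zero (possible with `koff_mut_multiplier = 0` and no
catalytically active ring) terminates the run early with a flagged,
shorter trace.

Time and ADP are recorded at every event; full species snapshots default
to every `n_steps/5000`-th event (the slope estimate is therefore
independent of the snapshot cadence; tests verify cadence-independence on
synthetic ramps). Burn-in is automated: the first half of the trace is
discarded, and the ADP slopes of the third and fourth quarters must agree
within 10% or the window carries a warning flag. k_obs is the
least-squares ADP slope over the window divided by the total number of
wild-type subunits.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| k12_f / k12_r | 0.009 / 3.5 | 1/(particle·s), 1/s | dimerization |
| k23_f..k45_f / _r | 0.012 / 3.0 | 1/(particle·s), 1/s | linear growth steps |
| k36_f, k46_f, k56_f / _r | 1.5 / 0.05 | 1/(particle·s), 1/s | ring closures |
| k_cat,WW | 5.0 | 1/s | fast wild-type turnover |
| k_cat,WM | 0.05 | 1/s | basal (inhibited) turnover |
| koff_mut_multiplier | 1.0 | — | mutant-interface dissociation factor |
| n_steps | 100,000 | events | trace length |

Rate constants are in per-particle units (arbitrary unit volume). The
default set is this package's own calibration, chosen once against
qualitative constraints: dimerization is the slowest forward step, the
monomer pool is the largest subunit class at n = 1000 with dimers more
populous than trimers (1–2–3–6) or tetramers (1–2–4–6), k_cat,WW is fixed
at the experimentally known 5 s⁻¹, turnover saturates with total particle
number, and the 1–2–3–6 pathway activates more steeply (lower
half-saturation) than 1–2–4–6. The working values were obtained by
balancing the steady-state fluxes at n = 1000 by hand and verifying the
pool ordering with the integrated ODE.

The basal rate deserves a note. With k_cat,WM ≳ 0.1 s⁻¹ the full-ring
scheme's titration curve is not monotone: past the inhibition plateau,
adding mutants keeps increasing the *total* particle number, which drives
more wild type into (basal-rate) rings, so k_obs creeps back up. That is
a genuine feature of coupling inhibition to assembly, not an artifact.
The default k_cat,WM = 0.05 s⁻¹ (a 100-fold reduction) keeps all three
schemes continuously falling over the default titration range, matching
the qualitative behaviour the model is meant to emulate; users probing
the creep-back regime can simply raise k_cat,WM.

## Fitting models

The binomial mixture model samples ring composition from the initial
subunit ratio with the mutant number weighted by an incorporation factor
d (m = d·n_M, p = m/(n_W+m)): mutant-free rings (probability
q⁶/(1−p⁶) among rings containing wild type) turn over at k_cat,WW, all
other wild-type-containing rings at k_cat,WM. Probabilities are at the
hexamer level, not weighted by wild-type count per ring. The generalized
non-competitive model is (S/(Km+S))·(k_cat,WW·Ki + k_cat,WM·I)/(Ki+I).
With S fixed (as in a mutant titration) this model is structurally
degenerate when k_cat,WW and Km are both free — only k_cat,WW·S/(Km+S),
k_cat,WM·S/(Km+S) and Ki are identifiable — so quantitative use requires
fixing k_cat,WW at its independently known value; the fitter supports
fixing any parameter subset and returns fixed values unchanged.

The pseudo-first-order prediction treats assembly as a linear chain of
enzyme states in which only the first forward rate is multiplied by S;
occupancies solve the stationary linear balance system (with catalysis
recycling the last state to the first), and the half-saturation constant
K is located by bracketed root finding on k_obs(S) = k_obs(∞)/2, where
the saturating limit is computed from the reduced chain with the first
state drained. The chain length is parametric (default matching
monomer→dimer→trimer→hexamer).

Least squares uses `scipy.optimize.least_squares` (trust-region
reflective, non-negativity bounds where physical, equal weights per
point). Non-convergence is reported in the result object, never raised
silently. "Systematic deviation" of a fit is a one-sided Wald–Wolfowitz
runs test on residual signs at α = 0.05.

## Sweeps and seeds

Sweeps derive each run's seed from (base seed, grid index, replicate
index) through `numpy.random.SeedSequence`, so any sweep is reproducible
and individual runs can be re-executed in isolation. Default grids:
concentration sweeps log-spaced over ~50–20,000 particles; mutant
titrations 0–10,000 mutants at n_Wt = 1000 with 5–10 replicates. The
validation suite uses 10 replicates of 300,000 events at 10,000 particles
for the mean-field comparison (the larger event count lets the faster
event clock at high particle number still cover the relaxation time) and
8 grid points × 5 replicates for the scheme-ordering titration; these
sizes give replicate standard errors well below the effects being
checked.

## What the synthetic data does and does not emulate

Synthetic titration curves add i.i.d. Gaussian noise to a chosen model
curve. Real titrations have concentration-dependent (typically relative)
noise, pipetting covariance between points, and systematic concentration
errors of tens of percent; recovery results on synthetic curves therefore
bound what is attainable under idealized noise, and say nothing about
robustness to systematic concentration miscalibration. Likewise the
simulator's agreement with its own census-weighted turnover is an
internal consistency check of the ADP accounting, not evidence that a
particular scheme describes any real enzyme.

## Numerical choices and degenerate inputs

Propensity evaluation is a full recompute per event (linear scan); with
≤ ~500 channels this is faster in compiled code than bookkeeping partial
updates. Exponential deviates use −log(1−u) to tolerate u = 0. Traces
shorter than 100 points raise rather than fit a slope; an all-mutant
system with locked interfaces absorbs into dead rings and is flagged.
All-parameters-fixed fits return residuals without optimization. The
ODE oracle integrates with LSODA at rtol 1e-10 to t = 3000 s, long past
the slowest relaxation at the default rates.

## Known limitations

- Two activity levels per wild-type subunit (fast/basal); no three-state
  or graded allostery, and no groups-of-three coupling.
- No spatial effects, no explicit nucleotide cycle, no force generation
  or substrate (e.g. microtubule) stimulation.
- The ring disassembles on every catalytic event; assembly and turnover
  are therefore tightly coupled, which is one specific (if convenient)
  reading of the catalytic step.
- Rate defaults are a calibration to qualitative constraints, not
  measured constants; quantities that depend on their absolute values
  (half-saturation constants, absolute k_obs) should be interpreted only
  relative to other simulations with the same set.
- Orientation-duplicate closure channels double the effective closure
  rate constant relative to a per-distinct-reaction convention; this is a
  pure rescaling absorbed by calibration but matters when comparing rate
  values with other codes.
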
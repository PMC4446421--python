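# Methods

## The design model

A regazyme is represented as an ordered list of named parts (5' leader,
transducer, ribozyme core with embedded aptamer, riboregulator,
terminator); the layout is configuration-driven, not hard-coded, because
constructs differ in how the designed arms flank the aptazyme. All
coordinates are 0-based half-open intervals; the cleavage site is a bond
index declared as a boundary between two named parts. The default order
places the mutable transducer 5' of the ribozyme core with cleavage at
the transducer|core boundary, so that the anti-seed leaves with the 5'
fragment and the seed (which must lie on the released 3' fragment; the
layout validator enforces this) is freed by cleavage. The seed and
aptamer regions are declared relative to their parts and mapped to
absolute coordinates per design, since the transducer length varies.
DNA input is transparently transcribed (T→U) on read. One or two
transducer segments may be mutable; single-nucleotide substitutions,
insertions and deletions are the move set, with moves that would leave
the length bounds excluded before drawing.

## Objective

Both conformational states are folded once per evaluation: the uncleaved
assembled RNA and the cleaved 3' fragment. The three penalty terms are
plain character-wise Hamming counts on dot-bracket strings — the aptamer
region against its target structure (uncleaved state), unpaired seed
positions pre-cleavage, paired seed positions post-cleavage — combined
as a weighted sum with default weights (1, 1, 1), since no principled
asymmetry between the terms is known. The catalytic-activation term is
operationalised purely as aptamer-structure distance: seed
exposure/obstruction is a secondary-structure property, whereas catalysis
proper involves tertiary contacts outside a secondary-structure model.
Free energies of both states are logged alongside the score but not
scored by default; an optional flag compares structures on the
paired/unpaired projection instead of the full {(,),.} alphabet.

## Folding engines

Two engines sit behind one contract (`mfe_fold`, `duplex`):

- **vienna** — nearest-neighbour thermodynamics via the ViennaRNA
  bindings; the engine version is recorded on the object since MFE
  structures drift across parameter sets.
- **toy** — maximum canonical pairing (Watson–Crick + G·U) with hairpin
  loops of at least three unpaired nucleotides, −1 kcal/mol per pair,
  and a fully deterministic tie-break: among maximum-pairing structures,
  scan 5'→3', prefer paired over unpaired, then the 5'-most partner.
  This rule is realised as a Nussinov-style dynamic program with
  deterministic traceback; the test suite re-derives it independently by
  exhaustive structure enumeration plus greedy filtering, exhaustively
  for all sequences up to length 7 and on seeded samples at lengths
  8–12. The toy duplex is the maximum non-crossing set of intermolecular
  canonical pairs between antiparallel strands (an alignment-style DP).

Pseudoknots are excluded throughout (standard secondary-structure
model). MFE structures only — the objective is structure-distance based,
so partition-function quantities are not needed.

## Annealer

Metropolis acceptance min(1, e^{−Δ/T}) with score-neutral moves always
accepted: the design space contains large plateaus of equally good
solutions and free plateau drift is what makes restarts productive.
Geometric cooling with defaults T₀ = 5 score units, factor 0.95 per
50-step stage, at most 20 000 iterations, early stop at score 0. These
defaults were chosen so that the enumerable toy problems converge in
well under a second; no claim is made that they are tuned for
full-length constructs, where users should lengthen the schedule.
Scores are memoized per transducer sequence (changes call counts, never
results). Restarts run with consecutive derived seeds and feed the
anchored-consensus analysis.

## Design-space statistics

Sarle's bimodality coefficient uses the sample-size-corrected form
BC = (g₁²+1)/(g₂ + 3(n−1)²/((n−2)(n−3))) with biased sample skewness g₁
and excess kurtosis g₂; the large-n uniform benchmark is 5/9, normal
1/3, balanced two-point → 1. The corrected form was chosen because
samples here are finite scores (n ≈ 1000); users wanting the population
form can compute it from the same moments. BC is applied per score axis.
The consensus is an ungapped anchor-registered alignment (first match of
an IUPAC anchor motif per sequence), because designed transducers vary
in length but share the anti-seed motif; per-column letters are the
IUPAC code of the observed base set, with modal-base conservation
fractions reported. Cross-talk screening evaluates duplex energies of
every mediator against every target 5'UTR and flags off-diagonal entries
within a margin (default 2 kcal/mol) of the cognate diagonal.

## Cleavage kinetics

f(t) = f₀ + (f_max − f₀)(1 − e^{−λt})^m, with f₀ the basal cleaved
fraction, f_max the plateau, λ (min⁻¹) the observed rate under
simultaneous production and degradation, and m a dimensionless temporal
exponent (1 for the small-molecule-sensing constructs, ≈2 for the
sRNA-sensing one, whose upstream sRNA induction adds a stage). Band
intensities are converted to fractions as c/(c+u). Fitting is bounded
nonlinear least squares (`scipy.optimize.least_squares`, trf) on
(f₀, f_max−f₀, λ[, m]), so the ordering constraint f₀ ≤ f_max is a box
bound; initial values come from the first point, the last point, and
the half-rise time; m is fixed to 1 or 2 by default because a free
exponent on six time points is weakly identified (a `free` mode fits it
within [0.5, 4]). λ is bounded to [10⁻⁴, 100] min⁻¹ as a plain numerical
guard. Residuals are unweighted by default; replicate SDs can weight
them.

**Identifiability caveat.** With sampling at t = 0, 2, 4, 8, 16, 32 min,
any rate whose rise completes within the first interval (λ ≳ 1 min⁻¹,
e^{−2λ} ≲ 0.1) is near-unidentifiable: whenever noise lifts the first
post-zero point above the fitted plateau, the likelihood is maximised at
arbitrarily large λ, so the least-squares estimator has a heavy right
tail and its mean diverges from the generating rate even though its
median recovers it. The fitter therefore reports a `rate_resolved`
diagnostic (false when λ̂ exceeds roughly 6 per first sampling interval
or sits at its bound) rather than attempting any correction; downstream
summaries of such fits should not use the mean. The self-consistency
tests recover rates to ≤0.1% noiseless across λ ∈ [0.05, 2] × m ∈ {1,2},
and the mean over 200 noisy replicates to ≤5% for the resolvable
conditions (0.15 and 0.17 min⁻¹); the 1.5 min⁻¹ condition is exactly the
unresolvable regime above and is reported as such.

## Cascade model

The minimal three-state reduction of the signaling pathway, built from
first-order kinetics with a quasi-steady-state treatment of translation
initiation:

    dRu/dt = β_R − (k(s) + δ_R)·Ru
    dRa/dt = k(s)·Ru − δ_R·Ra
    dG/dt  = α_G·Ra/(K_RU + Ra) − δ_G·G
    k(s)   = k_leak + k_cat·s/(K_s + s)

Defaults encode the measured time scales of the characterized system:
δ_R = ln2/2 min⁻¹ (≈2-min RNA half-life), k_cat = 1/6 min⁻¹ (≈6-min
cleavage characteristic time), δ_G = 1/12 min⁻¹ (≈12-min degradation of
the tagged reporter), K_s = 1 mM (effective signal dissociation
constant); β_R = 10 molecules/min, K_RU = 100 molecules and
α_G = 100 a.u./min are nominal scale choices that set only stationary
levels. The signal→cleavage coupling is single-site saturation because
the dose response is characterized by a single effective dissociation
constant. Signals are piecewise-constant (step / pulse / square wave);
integration (LSODA, rtol 10⁻⁸) restarts at every discontinuity so the
forcing is handled exactly. Steady states are closed-form; the 95%
response time is found by linear interpolation of the reporter crossing,
after checking that the final 5% of the grid varies by <1% of the total
change. Model structure reproduces the qualitative behaviour of the
measured system: the dynamics is governed by cleavage and reporter
degradation only (copy number, K_RU and the cleaved fraction move the
stationary level but shift the 95% time by <1%); with fast RNA turnover
the reporter collapses to exponential rise with production, and with
vanishing reporter degradation it grows linearly. With the default
6/12-min time scales the simulated 95% response to a step is ≈45 min —
slower than the ≈26 min observed in vivo for the best construct, as
expected for a naive two-stage reduction; resolving that gap would need
the unreduced reaction scheme and is out of scope.

Extrinsic cell-to-cell variability multiplies selected rates
(β_R, k_cat, α_G by default) by per-cell lognormal factors with mean 1
and a specified CV — the standard model of multiplicative parameter
variability; intrinsic molecule-number noise is out of scope. The
population CV is sd/mean of per-cell time-averaged reporter over an
ON-state window; since the stationary reporter is exactly linear in α_G,
α_G-only noise propagates to reporter CV identically, which the tests
use as a delta-method check.

## Synthetic data and what the tests show

The fixture generator emulates (i) an enumerable toy design problem —
a 17-nt regazyme with a 9-nt aptamer hairpin, GGG seed, and a 3-nt
transducer (64 candidates, 8 of them perfect anti-seeds) — verified
against brute force; (ii) gel-quantification time courses at
t = 0, 2, 4, 8, 16, 32 min for the three characterized conditions
(λ, m, f₀, f_max) = (0.15, 1, 0.30, 0.80), (1.5, 1, 0.30, 0.80) and
(0.17, 2, 0.01, 0.25), with Gaussian noise sd 0.05 / 0.05 / 0.02
clipped to [0, 1]; (iii) simulated single-cell ensembles. The synthetic
data are i.i.d. Gaussian around the model — real gel quantification has
correlated, heteroscedastic errors and model misfit, and real design
spaces are vastly larger with thermodynamic (not maximum-pairing)
folding — so passing tests demonstrate correctness of the algorithms
and estimators under the stated models, not predictive accuracy on new
constructs.

## Numerical choices and limitations

- Deterministic everything: one seeded NumPy generator per run; restart
  seeds are derived consecutively; fixture files are byte-identical per
  seed.
- Degenerate inputs are errors, not silent defaults: empty sequences,
  unbalanced or crossing structures, constant samples for BC, windows
  outside the simulated range, fewer than 4 (5 with free m) distinct
  time points.
- Tie-breaks: score-neutral annealing moves accepted; toy-engine
  structure ties broken 5'-most-first as above.
- The thermodynamic engine's structures (and hence scores) depend on the
  ViennaRNA version; the toy engine exists precisely so that the
  algorithmic tests are engine-version independent.
- No 3D/tertiary modelling, no pseudoknots, no partition-function
  ensembles, no stochastic chemical kinetics, no gel densitometry —
  band intensities and sequences are taken as given.
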
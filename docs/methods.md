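# Methods

## Scope and model family

`refugesim` studies how the topology of fitness trade-offs controls the
consequences of pest adaptation under the high-dose/refuge strategy. It
implements four layers around one bookkeeping identity — landscape
mortality is one minus the genotype-frequency- and area-weighted mean
survival:

1. a **static mortality surface** `M(phi)` over the resistant fraction;
2. a **discrete-trait recursion** (one locus, two alleles) for the
   resistance allele frequency;
3. a **quantitative-trait recursion** over a continuous trait with
   Gaussian habitat fitness functions;
4. **extensions** (habitat choice, phenotypic plasticity) that flatten
   trade-offs, and a **Wright–Fisher generator** providing the
   finite-population counterpart and a parameter-recovery harness.

## Discrete model

State is the resistance allele frequency `p`; genotype frequencies are
always the Hardy–Weinberg triple `(p², 2pq, q²)` in fixed row order
(RR, RS, SS). The life cycle is: zygotes at Hardy–Weinberg → dispersal
over habitats proportional to area → habitat-specific viability selection
→ a single panmictic mating pool → next zygotes. Survival (not mortality)
is the stored quantity because fitness composes multiplicatively on
survival.

Heterozygote survival defaults to per-habitat linear interpolation,
`s_RS,k = h·s_RR,k + (1−h)·s_SS,k`, with the dominance coefficient
`h ∈ [0,1]`; an explicit RS row overrides it. `h = 0` encodes the
functionally recessive resistance that high doses aim to create.

Population regulation is genuinely ambiguous in multi-niche selection
models, so both classic options are exposed:

* **hard**: survivors pool directly; `p' = (p²w_RR + pq·w_RS)/w̄` with
  `w_g = Σ_k f_k s_g,k`;
* **soft** (Levene): each habitat contributes offspring in proportion to
  its area; `p' = Σ_k f_k p'_k` over habitats with survivors, weights
  renormalized if a habitat's cohort is wiped out entirely.

The two coincide when one habitat holds all the area. They do *not*
coincide in general: notably, under the idealized strong symmetric
trade-off at refuge fraction 1/2, hard selection is exactly neutral
(every genotype's landscape-mean fitness is 1/2, so trajectories are
identical for every dominance coefficient), whereas soft regulation does
move the allele frequency (within-habitat survivor frequencies depend on
`h`). Realized landscape mortality is pinned at 1/2 in both regimes — the
flat-mortality law is about deaths, which regulation does not
redistribute.

Extinction (zero survivors landscape-wide, possible with idealized 0/1
matrices) is a first-class terminal state: trajectories truncate with an
explicit flag rather than dividing by zero.

A numerical note on near-fixation behaviour: for cost-free dominant
resistance the late-phase gain is `Δp ≈ ½pq²` per generation, so the
approach to fixation is slow — from `p₀ = 0.01` at refuge fraction 1/2
the recursion first exceeds 0.99 around generation 216.

## Quantitative model

The trait analogue uses Gaussian survival
`s_k(z) = s_max · exp(−(z−θ_k)²/2ω²)` with habitat optima `θ_k`, and a
Gaussian trait distribution `N(z̄, σ²_P)`. Opposing optima encode a strong
trade-off over a continuum; equal optima encode none. All stages are
closed form: mean survival in habitat k is
`s_max √(ω²/(ω²+σ²_P)) · exp(−(z̄−θ_k)²/2(ω²+σ²_P))`, and the
post-selection habitat mean is the Gaussian posterior mean
`(z̄ω² + θ_k σ²_P)/(ω²+σ²_P)`. Habitat means pool with weights
`f_k·E[s_k]` (hard) or `f_k` (soft); the response is the breeder's
equation `z̄' = z̄ + h²S` with phenotypic variance held constant (no
Bulmer effect — the simplest defensible recursion, a documented
limitation). The closed forms are verified against numerical quadrature
of survival times trait density.

These functional forms are this package's reconstruction choice: a fully
self-verifying Gaussian–Gaussian stack where every claim can be checked by
quadrature or grid search. Whether a linear-fitness or
truncation-selection variant would behave differently is untested here.

One geometric caveat: with symmetric optima `±a`, landscape survival as a
function of `z̄` is an even two-bump Gaussian mixture whose maximizer sits
slightly *inside* `±a` whenever the mixture is bimodal. The cap we assert
is therefore the provable one-sided bound
`max_z S ≤ ½·C·(1 + exp(−a²/2v))` with `C = s_max√(ω²/v)`,
`v = ω²+σ²_P` — comfortably below the no-trade-off ceiling `C`, which is
the scientific point: adaptation toward either optimum cannot restore
cost-free survival.

## Extensions: flattening trade-offs

* **Habitat choice** (`kappa ∈ [0,1]`): per-genotype occupancy is a linear
  mixture `(1−κ)·area + κ·(point mass on the genotype's best habitat)`,
  ties split by area. A single degree parameter is the minimal encoding of
  genotype–region covariation; it applies to all genotypes symmetrically
  (whether choice is genetically restricted is left open by the source
  material, and universality is the simpler assumption).
* **Plasticity** (`pi ∈ [0,1]`): survival entries mix toward their column
  maximum, `s̃_g,k = (1−π)s_g,k + π·max_g' s_g',k` — with probability π an
  individual expresses the locally best phenotype regardless of genotype.
  Plasticity acts on survival expression, not on genotype bookkeeping.

Both mechanisms only ever raise survival, so realized mortality is
non-increasing in κ and π; at κ = 1 or π = 1 the idealized strong
trade-off is fully flattened and mortality hits zero — the failure mode
that makes behavioural resistance and plastic expression dangerous for
trade-off-based control.

The implicit (dominance-resolved) RS row commutes with the plasticity
transform, so it can stay implicit: interpolating the modified homozygote
rows equals modifying the interpolated row, and the column maximum over
the three rows equals the maximum over the homozygotes.

## Wright–Fisher generator and parameter recovery

The stochastic generator reproduces exactly the statistical structure the
deterministic model assumes: each generation draws N zygotes multinomially
at Hardy–Weinberg, assigns them to habitats with probability equal to area
fraction, kills them independently with `1 − s_g,k`, and re-forms the next
generation at census size N from the survivors' allele frequency. One
global integer seed spawns independent per-replicate streams
(`numpy.random.SeedSequence`), so whole experiments reproduce
byte-identically. Extinction is a recorded outcome.

Runs record the habitat-stratified genotype cohorts (exposed and surviving
counts per generation, genotype and habitat) — what a field sampling
design stratified by crop region would observe. This matters for
identifiability: landscape-pooled allele-frequency changes cannot
determine the four homozygote survival entries at all. The hard recursion
is invariant to a common rescaling of all survival entries, pooled
frequencies expose only the area-weighted genotype means, and in the
strong-trade-off benchmark at refuge fraction 1/2 the pooled dynamics are
exactly neutral — zero signal. `fit_survival` therefore solves a bounded
linear least-squares problem (scipy `lsq_linear`, box constraints [0,1])
on cell-level survival: predicted survivors are `exposed · s_g,k`, with
heterozygote cells tied to the homozygote unknowns through the supplied
dominance coefficient. Joint estimation of survival *and* dominance is not
attempted — it is unidentifiable from short series in wide parameter
regions — and entries whose design column is identically zero (a genotype
never exposed in a habitat, e.g. susceptibles in a fixed-resistant
population) are flagged inestimable rather than guessed.

On noise-free expected cohorts the fit recovers the generating entries to
numerical tolerance; under the stochastic benchmark (50 replicates,
N = 10⁴, survival 0.9/0.1, 30 generations) it recovers them within ±0.05.

## What the generator does and does not emulate

It emulates multinomial reproduction, area-proportional exposure and
independent binomial survival — the assumptions under which the
deterministic recursion is the infinite-N limit (verified: the
replicate-mean trajectory at N = 10⁵, 200 replicates tracks the recursion
within 0.01 per generation). It does **not** emulate overlapping
generations, spatial clustering within habitats, density dependence,
mutation, migration between farms, measurement error in genotyping, or
temporally varying survival. Tests passing on this generator show the
pipeline is internally consistent, not that field data satisfy these
assumptions.

## Yield mapping

Yield is a dimensionless index `1 − max_loss·(1 − M)`, linear in pest
survivorship. The default `max_loss = 0.36` is the upper bound of the
widely cited 9–36% range of potential yield loss to animal pests; it is a
bound on the scale of the index, not an estimate for any particular crop.
Nonlinear compensatory-growth responses are deliberately not implemented;
the `YieldModel` seam is where a crop-specific curve would plug in.
Coupling camouflage effects to absolute yield gains requires external
herbivory–yield slopes and is out of scope.

## Scenario presets and numerical choices

* `figure2`: the two idealized mortality curves over a φ-grid of 101
  points on [0,1] at refuge fraction 1/2 — the package's desk-scale
  headline numbers (50/25/0% versus flat 50%).
* `camouflage_3fold`: a colour-intercropping scenario with survival 0.75
  on the matched crop colour versus 0.25 on the mismatched one — a 3-fold
  ratio encoding the reported 3-fold abundance advantage of well
  camouflaged herbivores. Its outputs illustrate the strong-trade-off
  regime with imperfect (non-0/1) survival; they are not field estimates.

Tolerances: exact closed-form identities are asserted at 1e-12; the
recursion is checked against an exact-rational cohort-enumeration oracle
at 1e-10 per step; Gaussian closed forms against quadrature at 1e-6.
Probability-simplex sums are validated at 1e-12. Ties in habitat choice
are resolved within 1e-12 of the row maximum. Frequencies are clamped to
[0,1] after each step to absorb last-bit rounding.

Default study conditions used by the test suite: mean-field check at
N = 10⁵, 50 generations, 200 replicates; recovery benchmark at N = 10⁴,
50 replicates, 30 generations; neutral-drift and variance-scaling checks
at N ∈ {100, 1000, 10000} with a few hundred replicates. These sizes make
the stochastic claims sharp while keeping the whole suite fast.

## Known limitations

Single locus, two alleles; no mutation, drift (outside the generator),
migration, age structure, or multi-farm space. Phenotypic variance is
constant in the quantitative model. Habitat choice and plasticity are
universal, not genotype-restricted, and do not themselves evolve.
Compensatory evolution along novel trait axes (e.g. behavioural escape
from visual predators) is discussed in the source literature but has no
mechanistic model here.
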
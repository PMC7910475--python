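# Methods

## Forward consumer-resource model

The model (`gutcp.trophic_model`) propagates a fixed nutrient intake
through `n_levels` discrete trophic levels. Per level, each metabolite
with a positive available amount is consumed *entirely* by the set of
present species holding a consumption link for it (all-or-nothing
uptake), split in proportion to their measured relative abundances —
not model-grown abundances, so each sample's prediction is driven by its
own composition. A consumer converts the fraction 1 − f of its intake
into growth and secretes the fraction f, divided equally across all its
production links, into the next level's pool.

Parameters:

| parameter | default | meaning |
|---|---|---|
| `byproduct_fraction` f | 0.9 | fraction of consumed flux re-secreted; (1 − f) is the growth yield. The default is configurable; benchmark instances use f = 0.5 and state it explicitly. |
| `n_levels` L | 4 | trophic depth; four levels match the observed layering of gut cross-feeding from dietary polysaccharides down to terminal byproducts. |
| `detection_floor` ε | 10⁻⁶ | predicted level below which an entity counts as absent; also the floor substituted for predicted zeros inside logarithms. |
| `carry_through` | True | whether unconsumed metabolites stay in the pool at later levels. |

Two conventions and one edge case are worth recording:

- **Carry-through is vacuous here.** Because uptake is all-or-nothing
  and species presence and links are fixed within a pass, a metabolite
  either has a present consumer (and is drained at first exposure) or
  never acquires one. Re-offering leftovers at later levels therefore
  changes nothing; the flag exists for interface completeness and a test
  asserts the equivalence on random instances.
- **Terminal consumers.** A species with no production links routes the
  byproduct share of its intake to growth (yield 1). The alternative —
  letting that flux vanish — would break exact mass balance
  (sum(diet) = sum(growth) + sum(metabolome)), which the implementation
  maintains to machine precision and the tests enforce at 10⁻⁹ relative.
- **Monotonicity caveat.** Adding a consumption link can *raise* the
  consumed metabolite's predicted level when the consumer also produces
  it (a bidirectional pair) or when a production path cycles back. The
  intuitive "a new consumer drains its metabolite" property holds only
  for consumers with no production links, and is tested in that form.

## Bias and performance metrics

The systematic bias of entity i is the mean over samples of
log10(predicted/measured), restricted to samples where the measured
level is positive (measured zeros carry no scale information and are
excluded); predicted zeros are floored at ε. Performance is summarized
by (1) the per-sample Pearson correlation of log10 levels over the
overlap set, averaged over samples (a pooled variant is available),
(2) the mean absolute log10 error over sample × overlap-metabolite
pairs, and (3) the overlap count itself — metabolites predicted above ε
in ≥ 1 sample and measured above zero in ≥ 1 sample (the per-sample
median is also reported).

Because measured metabolomes are relative while the forward model emits
flux units, the error metrics optionally renormalize each sample's
predicted and measured vectors to sum to 1 over the overlap set before
comparing logs (`normalize=True`, the mode the inference loop uses).
The correlation is invariant to such per-sample rescaling, so it takes
no flag. With `normalize=False` raw values are compared; the formula
examples in the tests use this mode.

## Link inference

One run alternates: compute biases → build a categorical prior over all
candidate links → propose one → re-run the forward model → accept by
Metropolis → repeat. Priors are recomputed only after an accepted move,
since biases depend only on the network. Consumption and production
weights are normalized jointly into a single proposal distribution.

Design choices made where the procedure was genuinely open:

- **Bias saturation in priors (`bias_cap`, default 1.0).** An entity
  predicted at the detection floor has a formally huge |bias| (≈ 5 log
  units at ε = 10⁻⁶), and e^{γ·|b|} would concentrate essentially all
  proposal mass on that single entity's candidates, starving the uniform
  κ mixing that lets the search reach indirect repairs. Biases are
  therefore clipped to ±1 order of magnitude inside the prior only —
  beyond that, a bias indicates direction, not additional evidence.
  Measured effect on the recovery benchmark: without the cap the search
  deadlocks (total prior mass on objective-improving candidates ≈ 10⁻⁵,
  best E ≈ 0.23 versus an attainable −0.015); with it, runs reach
  near-optimal objectives and recover most withheld links.
- **Metropolis completion.** Acceptance uses min(1, e^{−ΔE/kT}), so
  improvements are always kept; 1/kT defaults to 5000. Temperatures
  matched to this benchmark's larger per-move |ΔE| (1/kT ≈ 10–1000)
  were evaluated and did not help — the binding constraint is proposal
  allocation, not acceptance — so the default is used everywhere.
- **Stopping rule.** Before the loop, 50 uniformly random candidates
  are probed at the initial network; the baseline drift is
  window × mean over probes of ΔE·e^{−ΔE/kT} taken over *worsening*
  probes only. A random probe that happens to improve the objective is
  signal the search should pursue, not part of the noise floor; counting
  it (as a naive "mean |ΔE| × acceptance fraction" does) makes the
  baseline exceed the total achievable improvement at a badly degraded
  starting network and stops every run at the first window check. The
  run stops when |E(t) − E(t − window)| ≤ baseline (window 500 by
  default), with `max_iter` (default 20,000) as a hard budget.
- **Removal moves** (off by default) make each iteration an add-move
  with probability 0.5, otherwise a uniformly chosen existing link is
  proposed for removal; removing a previously added link refunds its
  λ_reg penalty. Equivalent repairs exist (removing the production link
  a junk consumer feeds on also zeroes the error), so removal runs are
  validated on the contract — removed links leave the network, the
  objective never ends above its start, and the planted junk link is
  itself dropped in a substantial fraction of seeds.
- Each run returns the **best-objective network visited**, not the last
  one, and the reported trajectory ends at exactly the value that
  re-evaluating the returned network reproduces.

## Consensus atlas

Prevalence is the fraction of runs containing a link; the null
probability of chance discovery is q = (mean added links per run) /
(candidate-space size), and each link's P value is the exact one-sided
binomial tail P(X ≥ k), X ~ Binomial(R, q), computed via the regularized
incomplete beta function and cross-checked in the tests against an
independent term-by-term log-space summation to 10⁻¹². The default
atlas threshold is P < 10⁻³. Bidirectional pairs are kept as two
directed links; a reporting helper collapses a pair to the direction
with the smaller P value.

## Synthetic data generator

`generate_truth_network` builds a layered network: metabolites are
assigned to levels 0..L (level 0 is the diet set, every level
non-empty), each species gets a home level with one consumption link
there and one production link to the next level, plus random extra
links (consuming from its level or below, producing to levels above) up
to `links_per_species`. Every metabolite above level 0 is guaranteed a
producer, so the whole network is reachable from the diet.

`simulate_dataset` draws species presence independently per sample
(Bernoulli with probability `species_prevalence`), gives present
species log-normal abundances (σ = 1 in natural log) normalized per
sample, runs the forward model under the truth network, and multiplies
each measured level by 10^N(0, noise_sd) — multiplicative log-normal
noise, the standard model for metabolomics intensities. Predicted zeros
stay zero. `withhold_links` removes a fixed fraction of links by a
greedy feasible draw along a random permutation, keeping every
metabolite's producer set and every consumer's diet non-empty (those
removals would make parts of the truth unreachable rather than merely
unknown).

What the generator does *not* emulate: compositional sequencing noise,
detection limits in the metabolome, real taxon/metabolite identities,
sample covariates, or any violation of the forward model itself. A
passing recovery benchmark therefore shows that the inference machinery
can find links whose absence measurably distorts predictions under the
model's own dynamics — not that the model family is adequate for any
particular real dataset.

## Benchmark and evaluation sizes

The frozen recovery benchmark (`BENCHMARK1`) uses S = 10 species,
M = 20 metabolites, 3 trophic levels (+1 terminal), 3 links per
species, 30 samples at prevalence 0.8, noiseless measurements, f = 0.5,
15% of links withheld, and a 20-run ensemble with per-run budget 8,000
iterations; recovery is scored over five instance seeds. Cross-validated
generalization uses 4 folds with 5 runs per fold and a 4,000-iteration
budget per run, over 20 replicates in the tests (10 in the acceptance
script). These sizes were chosen so the whole evaluation completes in a
few minutes on one CPU while leaving the conclusions seed-stable.

Hyperparameter calibration sweeps λ_reg over {10⁻⁴, 10⁻³, 10⁻²} and
λ_reward over {10⁻⁴, 10⁻³, 10⁻², 10⁻¹} (decade steps), a 3 × 4 grid
containing the default cell (10⁻³, 10⁻³).

## Known limitations

- The search is greedy-stochastic; distinct runs can settle on
  flux-equivalent alternative explanations (e.g. a different producer
  feeding the same downstream pool). The consensus step is the defense,
  and the recovery benchmark's AUC measures exactly how well it ranks
  true links above such alternatives.
- The objective scores metabolites only; species-level biases influence
  proposals but not acceptance. A flag-level extension to add a species
  error term is straightforward but deliberately not enabled.
- Raw one-sided P values are thresholded without multiple-testing
  correction across links, matching the consensus design; an FDR layer
  would be a natural extension.
- Entity name alignment between network and dataset is exact matching
  after case-folding and whitespace trimming; no taxonomy or synonym
  resolution is attempted.
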
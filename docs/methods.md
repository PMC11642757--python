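# Methods

## Generative model

**Lineage.** An embryo is the result of 8 synchronous division rounds
(2⁸ = 256 cells) with binary per-cell ploidy. With probability `meiotic`
the zygote is aneuploid and so is every descendant. Otherwise the euploid
cell count evolves by the branching recursion `E ← Binomial(2E, 1 − p)`
per round (`p` = `mitotic`): every daughter of a euploid cell is
independently corrupted with probability `p`, and aneuploid clones breed
true. Two conventions are supported for how a mitotic error hits a
division:

- `per_daughter` (default): each daughter independently;
- `per_division_both_daughters`: the division errs as a whole and both
  daughters are aneuploid.

Both give the same per-cell marginal euploid probability (1 − p)⁸ and the
same expected aneuploid fraction `m + (1 − m)(1 − (1 − p)⁸)`; they differ
in clone-size correlation. `per_daughter` is the default because it
reproduces the observed order of magnitude of fully euploid embryos in
posterior predictive samples (P(fully euploid | no meiotic error)
= (1 − p)^510, with 510 = Σₖ₌₁⁸ 2ᵏ daughter draws).

**Geometry and dispersal.** Cells occupy a deterministic Fibonacci lattice
on the unit sphere, a stand-in for the trophectoderm shell; every cell's
neighbor ordering is by chordal distance with ties broken by cell index.
Aneuploid cells are placed by seed-and-grow: `s = max(1, round(d · n_an))`
seed cells are drawn uniformly without replacement, then clusters grow one
cell at a time (cluster chosen uniformly at random; the grown cell is the
nearest unmarked cell in that cluster seed's neighbor ordering) until
`n_an` cells are marked. `d = 0` yields a single contiguous patch; `d = 1`
makes every aneuploid cell its own seed, i.e. a uniform random subset, so
the biopsy count is exactly hypergeometric. The mechanism at intermediate
dispersal is this package's own construction — the published spatial
simulator it emulates does not document its internals — so quantities at
`d` = 0 and 0.5 carry extra model uncertainty, which is why the test suite
checks `d = 0` behavior qualitatively (patch connectivity, correlation
sign) rather than numerically.

**Biopsy and classification.** A biopsy is an index cell plus its
`biopsy_size − 1 = 4` nearest neighbors. Classification uses the
aneuploid-cell proportion with exact integer arithmetic: <20% euploid,
20–70% mosaic (both ends inclusive), >70% aneuploid. The alternative rule
`any_but_not_all` (mosaic iff some but not all cells are aneuploid) is
available; for 5-cell biopsies the rules disagree only at 4/5 aneuploid
cells, and swapping them changes fitted posteriors negligibly at high
dispersal, so the threshold rule is used throughout by default.

## Inference

Adaptive population Monte Carlo ABC with uniform(0, 1) priors (open at the
boundaries) on both rates:

1. Draw N particles from the prior, simulate a trial per particle
   (`n_embryos_per_trial` lineages, biopsy classes sampled from the
   class-probability lookup), and keep the `⌈αN⌉` particles whose summary
   triple lies closest (Euclidean distance on raw proportions) to the
   target. Their largest distance is the first tolerance ε₁.
2. Each iteration replenishes the population with `N − ⌈αN⌉` proposals:
   resample retained particles by weight, perturb each coordinate with a
   Gaussian kernel whose per-coordinate variance is twice the weighted
   empirical variance of the retained set, redraw anything outside (0, 1)².
   Proposal weights are prior density over the weight-normalized
   kernel-mixture density. Merge, re-cull to `⌈αN⌉`, record
   εₜ = largest retained distance and p_acc = the fraction of fresh
   proposals beating εₜ₋₁.
3. Stop at p_acc ≤ 0.05 (or the safety cap of 60 iterations; full-scale
   fits stop by p_acc after ~35–40).

Defaults `N = 2000`, `α = 0.5` retain 1,000 particles; the retained set is
the posterior sample, summarized by weighted means and weighted
equal-tailed 95% intervals (cumulative-weight interpolation, stable sort,
lower tie index). No post-hoc regression adjustment is applied: the
importance weighting of the adaptive scheme is the only correction.

**Lookup acceleration.** The class of the default-index biopsy depends on
the embryo only through `(n_aneuploid, dispersal)`. Per dispersal a
257 × 3 table of class probabilities is precomputed — exactly (from the
hypergeometric distribution) at `d = 1`, from 2,000 Monte Carlo placements
per row otherwise — and ABC trials sample classes from it. Agreement with
the direct placement pipeline is enforced by test.

## Target data

The study catalog freezes four published biopsy-class triples
(euploid/mosaic/aneuploid): 0.232/0.187/0.581 (n = 6,766 biopsies; also
kept in rounded two-digit form), 0.49/0.18/0.33, 0.53/0.15/0.32 and
0.51/0.06/0.43. The precise triple is the default ABC target for the first
study. Synthetic targets are produced by the forward simulator at known
rates, either with multinomial noise at a finite biopsy count or in a
noise-free limit (10⁵ simulated biopsies); recovery tests default to
noise-free targets so credible-interval coverage reflects ABC error rather
than target noise.

## Posterior predictive analysis

1,000 weighted-with-replacement posterior draws × 1,000 embryos each
(10⁶ embryos per dispersal). An embryo is fully euploid at 0 aneuploid
cells, fully aneuploid at 256, mosaic otherwise. The first biopsy is
anchored at the geometry's default index cell, the second at a uniformly
drawn index cell; both use the threshold classification. The second biopsy
may overlap the first (the simulated embryo is left intact; a no-overlap
option restricts the second index cell to positions with disjoint biopsy
sets). Aneuploid-fraction histograms are kept at exact per-count
resolution (257 bins) with a 20-bin export for plotting. "Unique embryos"
means independent simulations; no deduplication is attempted.

## Robustness analyses

*Misclassification*: a fraction r of the mosaic target proportion is
reassigned evenly to euploid and aneuploid (adjusted triple
`(e + rm/2, m(1 − r), a + rm/2)`, exact arithmetic), the posterior is
refitted and the predictive embryo composition recomputed; the sweep grid
is r = 0, 0.1, …, 1.0. *Battery*: every catalog study × dispersal
combination is refitted and summarized in one table.

## Numerical and design choices

- All randomness flows through an injected `numpy.random.Generator`; the
  sequential placement loops are numba-compiled but consume uniform
  variates precomputed by that generator, so every pipeline stage is
  reproducible from one seed. Large batches are processed in fixed-size
  chunks to bound memory.
- Classification thresholds compare `10·count` with `2·size` / `7·size`
  to avoid floating-point edge effects at 1/5 = 20%.
- Seed counts use round-half-away-from-zero and are clamped to `n_an`;
  degenerate placements (0 or all cells) bypass the spatial machinery.
- Kernel variances are floored at 1e-20 to survive degenerate retained
  sets; non-finite importance weights raise with diagnostics rather than
  propagate.
- Proposals outside the prior support are redrawn (truncation with
  renormalized kernel), keeping the population size fixed.

## What the synthetic data do and do not establish

The generator emulates the *reported class proportions* of clinical PGT-A
under an idealized embryo: synchronous divisions, a fixed mitotic error
probability across all divisions, binary ploidy without chromosome
identity, gains/losses, rescue events, or selection against aneuploid
cells, and a biopsy that samples the shell without technical noise.
Passing recovery tests therefore show that the inference machinery can
recover the parameters *of this model class* from proportion data — not
that real embryos satisfy the model. In particular, inferred rates absorb
any ascertainment bias of clinically biopsied (morphologically selected)
blastocysts.

## Known limitations

- The intermediate-dispersal placement mechanism is a documented stand-in;
  absolute numbers at dispersal 0 and 0.5 shift with its details, and the
  dispersal-1 fit concentrates the mitotic posterior ~0.2–0.3 percentage
  points above values obtained with a more even ("maximum separation")
  spatial spreading, because uniform random placement detects low-level
  mosaicism slightly less efficiently per unit error rate. Quantities
  downstream of the mitotic rate (fully-euploid predictive proportion,
  high-misclassification refits) inherit this sensitivity.
- A single mitotic error probability is shared by all division rounds,
  although early cleavage divisions are empirically more error-prone.
- Biopsy size is fixed at 5 cells; no inner-cell-mass biopsy and at most
  two biopsies per embryo are modelled.
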
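# Methods

## The screening model

Each expression feature `x` (log-scale intensity) is tested for a monotone
association with age at diagnosis, separately within tumor and within
non-neoplastic samples. Age is continuous by construction:
`(diagnosis − birth) in days / 365`. The divisor is the plain constant 365 —
not 365.25 — because the convention only matters at day resolution, and day
resolution is exactly what guarantees distinct ages. Distinct ages matter
statistically: with a tie-free covariate the null distribution of Spearman's
ρ is the pure permutation distribution, so small-sample p-values can be made
exact rather than asymptotic.

Spearman's ρ uses mid-ranks; without ties it reduces to
`1 − 6Σd²/(n(n²−1))`, and the implementation switches to that closed form
when both vectors are tie-free to avoid floating-point cancellation.
Constant vectors have no rank ordering: ρ is undefined and the feature is
reported but excluded from classification.

## p-values: exact, Edgeworth, t

Two-sided p is `min(1, 2 × smaller tail)` of the null distribution of
`S = Σd²`, the observed value included (so ρ = 0 gives p = 1). Three
branches, recorded per result in the `method` column:

- **exact (n ≤ 10 by default, hard ceiling 13).** The full null distribution
  of S is computed by a subset dynamic program: positions are filled in rank
  order, a bitmask tracks used ranks, and partial-sum histograms are shifted
  by each squared displacement. The result is identical to enumerating all
  n! permutations at O(2ⁿ·n·S_max) cost; counts are exact int64 (13! ≈
  6.2×10⁹ ≪ 2⁶³). Distributions are cached per n.
- **edgeworth (n ≤ 1289 by default).** S is symmetric under the null, so the
  skewness term of an Edgeworth expansion vanishes and the first correction
  involves only the excess kurtosis:
  `F(s) ≈ Φ(z) − φ(z)·(γ₂/24)·(z³ − 3z)`, with `z = (s + 1 − μ)/σ` (S moves
  on a lattice of spacing 2, hence the half-step `+1` continuity
  correction), `μ = n(n²−1)/6`, `σ² = n²(n−1)(n+1)²/36`, and the exact
  closed form `γ₂(n) = −(114n² + 30n − 216) / (25·n(n−1)(n+1))`. That
  closed form was obtained by exact rational interpolation of the enumerated
  null distributions for n = 4…13 (Fraction arithmetic; it reproduces all
  ten enumerated kurtoses exactly, including held-out n). Against the exact
  distribution the approximation errs by < 4×10⁻³ at n = 12–13 and shrinks
  with n; at n = 49 it sits within ~1 Monte-Carlo SE of a 200,000-draw
  permutation estimate.
- **t_approx (beyond).** `t = ρ√((n−2)/(1−ρ²))` on n−2 degrees of freedom —
  the standard large-sample route; adequate there, measurably worse than the
  Edgeworth branch at moderate n.

Both branch points are configurable; the Edgeworth cutoff default mirrors
widespread statistical-package practice. Expression values (unlike ages) may
contain ties; mid-ranks are used, the row is flagged `ties=True`, and the
p-value is then approximate — the S lattice argument assumes tie-free data.

## Classification and the tumor-specific rule

A feature is positively age-correlated when `ρ > ρ_min` and `p < α`
(strictly), anti-correlated when `ρ < −ρ_min`; defaults α = 0.05,
ρ_min = 0.3, applied per tissue with nominal p-values (no FDR — the screen
is deliberately a nominal-level filter). A tumor-classified feature becomes
a *tumor-specific candidate* when its normal-tissue p ≥ `normal_p_floor`
(inclusive). Two floors are in legitimate use: 0.05 (the default here) and
the stricter 0.4; both are exposed. Features unmeasured (or constant) in
normal tissue cannot be judged tumor-specific and are reported as
ineligible rather than silently promoted — the conservative reading.

The floor trades sensitivity against exclusion. With 15 normal samples and a
true within-normal correlation of 0.6, the normal-tissue test only reaches
p < 0.05 about 65% of the time, so ~35% of genuinely both-tissue features
leak through a 0.05 floor; a 0.4 floor excludes ~94% of them but discards
40% of true tumor-only candidates (null p ≥ 0.4 has probability 0.6). No
floor does both well at that normal-sample size; the acceptance suite
measures both operating characteristics at the default and the planted-signal
exclusion check documents this power ceiling rather than hiding it.

## Integration

For each candidate miRNA, its annotated targets (pair table pre-filtered to
the measured gene universe; dropped pairs counted) are tested for
anti-correlation across the shared **tumor** samples — the candidate set is
tumor-derived, so tumor scope is the default, with an all-samples switch.
Matrices are aligned by sample id, never by column position. Edges require
`ρ < 0` (strict) and `p < α`; no magnitude threshold is applied — the 0.3
modulus belongs to the age screen, not the network — though a `rho_max` knob
exists for sensitivity analyses. Edge weight is ρ; exports carry
`width = |ρ|` for renderers. The network is bipartite by construction and
every node touches at least one edge; genes targeted by several miRNAs are
shared nodes and edges are distinct (miRNA, gene) pairs.

## Synthetic cohorts

The generator emulates the statistical structure of the motivating cohort —
49 tumor + 15 normal samples, 1,710 miRNAs, 18,531 genes, ages ~1–35 y — with
a scaled-down preset (200 miRNAs, 2,000 genes) for fast tests. Defaults
plant 39 positively and 20 negatively age-correlated features per matrix
plus 10 tumor-only candidates, at Spearman strength 0.6 — a mid-strength
choice, well above the 0.3 screen threshold yet far from deterministic at
n = 49; real effect-size distributions are unknown, so these defaults are
plausible rather than fitted.

- **Ages** are drawn uniformly over the configured range on the day grid,
  without replacement — distinctness is guaranteed, not merely probable.
  Birth/diagnosis dates are back-computed so the metadata round-trips
  through the age formula exactly.
- **Planted features** are `baseline + noise_sd·(r·g(age) + √(1−r²)·ε)` with
  `g` the Blom normal scores of age (any rank-preserving transform would do —
  Spearman is invariant) and `r = 2·sin(π·ρ_s/6)`, the inverse of the
  bivariate-normal relation `ρ_s = (6/π)·arcsin(r/2)`. This calibrates the
  expected sample Spearman to `ρ_s` in closed form; a 100-replicate
  Monte-Carlo test confirms the ρ = 0.8 setting lands within ±0.15.
- **Tumor-only features** receive the age signal in tumor columns only
  (alternating signs); their normal columns stay i.i.d. noise.
- **Repression**: each tumor-only miRNA suppresses `targets_per_mirna / 2`
  reserved background genes via the same construction against the miRNA's
  per-tissue normal scores, sign negative, strength = target |Spearman|
  (default 0.6). The target table mixes these true pairs with decoy pairs to
  independent-noise genes, so the sign/significance filter is actually
  exercised; mean out-degree of planted miRNAs ≈ `targets_per_mirna`.
- **Determinism**: one master seed; all sub-streams are fixed-index children
  of its SeedSequence. Identical configs produce byte-identical files.

What the generator does *not* emulate: probe-level artifacts, batch effects,
normalization residue, correlated background features, or realistic
miRNA-target topology (one repressor per planted gene). Passing recovery
tests therefore demonstrates correctness of the statistical machinery under
the stated model, not robustness to microarray preprocessing.

## Other components

- **2^−ΔΔCt**: per-record ΔCt = Ct_target − Ct_reference; fold change
  2^−(ΔCt_sample − ΔCt_calibrator). Group summaries compare mean ΔCt per
  group — the geometric-mean-of-quantities convention, standard for this
  method (the arithmetic mean of per-sample folds is biased upward). No
  efficiency correction.
- **Cohort tables**: counts and within-column percentages (overall / PEDS /
  AYA), NA as its own category, rounded half-away-from-zero (9/21 → 43).
  Published tables of this kind are not always internally consistent in
  their rounding; this package applies one rule uniformly.

## Numerical and design notes

- Edgeworth tails are clipped to [tiny, 1]; p-values never return exactly 0.
- Problem sizes in the test and acceptance runs — 200,000 permutation draws,
  1,000 null features, 100 recovery replicates at 200 miRNAs, one full-scale
  (1,710 × 18,531) pipeline pass — were chosen so the whole battery
  completes in seconds while keeping Monte-Carlo error well below every
  asserted tolerance.
- Gene-level screening applies the same classification; the tumor-specific
  filter is optional for genes (off by default in the CLI) since candidate
  selection is a miRNA-level concept here.
- Exit codes: 0 success (an empty network is a success with a warning),
  2 usage/config errors, 1 data errors.

## Known limitations

- The exact branch is capped at n = 13 by int64/memory; beyond that the
  Edgeworth branch is the accuracy workhorse.
- With tied expression values all p-value branches are approximations;
  only the tie flag records this.
- The candidate rule's power asymmetry at small normal-sample counts (see
  above) is a property of the design being modeled, not of the
  implementation; plan normal-tissue sample sizes accordingly.
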
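# Methods

## The model

`kinsim` simulates the multi-level evolution of kinship structures.  The
agent is the *family*, characterized by a two-dimensional cultural trait
`t = (t1, t2)` and mate preference `p = (p1, p2)`; the first component
of each is transmitted through the paternal line, the second through the
maternal line.  Families live inside societies; `N_s` societies compete.

Within a society Φ, family *i*'s social relations are Gaussian kernels
with tolerance τ:

- cooperation with *j*:
  `exp(-min(|t_i - t_j|, |t_i - p_j|, |p_i - t_j|)² / τ²)` — cultural kin
  and mates (in either direction) are cooperators; `friend_i` is the
  society average (self-term included, which also makes singleton
  societies well defined);
- competition with *j*: `exp(-|p_i - p_j|² / τ²)` — families courting
  the same grooms are rivals; `rival_i` is the society average;
- growth: the numbers of sons and daughters that survive to
  marriageable age are independent Poisson draws with mean
  `r = b · exp(-d_c (1 - friend_i) - d_m · rival_i)`.

One step is one generation: (1) every family founded by last round's
marriages draws its offspring; (2) unmarried men, in random order, each
offer to one family sampled with probability
`∝ exp(-|t_groom - p_bride|² / τ²)` over the whole society — the offer
fails if the sampled family holds no unmarried woman; each marriage
consumes one man and one woman (monogamy; marrying into one's own
family is allowed) and immediately founds a child family with
`t = (t1_groom, t2_bride) + η_t`, `p = (p1_groom, p2_bride) + η_p`,
all four noise components i.i.d. Normal(0, μ²); (3) unmarried members
age; those unmarried for `unmarried_lifespan` (default 2) rounds die
childless, and families with neither unmarried members nor a pending
brood are dropped; (4) any society reaching
`split_threshold_factor · N_f` (default 2·N_f) families splits uniformly
in half and a victim society — uniform among all others, extinct ones
included — is removed, keeping exactly `N_s` societies.  Step (4) is the
group-level selection: fast-growing societies replace others.

Defaults (`ModelParams`): b = 5.0, μ = 0.1, τ = 1.0, N_f = N_s = 50,
500 steps.  `d_c` (cost of lacking cooperators) and `d_m` (cost of
rivals) are the environmental axes of every experiment.

### Design choices the rules leave open

- **Offer semantics.** Offers are sampled from the *full-society*
  distribution and fail when the target family has no unmarried woman,
  rather than being restricted to families that still have one.  The
  restricted variant was implemented first and discarded: with balanced
  sex ratios it marries essentially every woman regardless of how her
  family's preference is placed, which removes bride-side selection;
  preferences then drift off all traits along male lines (rivalry is
  escaped for free) and no coherent clan structure can form.  With
  fail-on-miss, families whose preferences sit on nobody's traits draw
  no offers and lose their maternal line — the pressure that keeps each
  clan's preference pinned to another clan's trait.
- **Who reproduces.** Only newly married couples bear children; founding
  families are treated as just-married couples, so the first offspring
  appear at step 1.  Families whose members all married or died are
  dropped; families still holding unmarried members stay in Φ (they
  count for friend/rival and can receive offers) until emptied.
- **Cohort consumption.** A marriage removes the oldest unmarried member
  of the family first (members are otherwise exchangeable; taking the
  member closest to dying is the only non-arbitrary rule).
- **Step order.** reproduce → marry → cull → split, per society, with
  all randomness drawn from a single seeded generator in a documented
  order (see `kinsim.engine`); identical parameters and seed give
  bit-identical trajectories.
- **Splitting.** If growth overshoots, halves can themselves exceed the
  threshold; splitting repeats (choosing uniformly among oversized
  societies) until none remains at threshold, one victim per split.
  Both halves inherit the parent's `lineage_id` so event logs can
  follow a society through splits.

## Clan detection and classification

The final (t, p) cloud of the most populous surviving society is
clustered in the raw joint 4-D space: k-means for k = 1..8 (10 seeded
restarts each) scored by the spherical-Gaussian BIC (Pelleg–Moore form),
then clusters whose centroids lie within τ of each other are merged
(single linkage, size-weighted centroids).  Raw units rather than
per-dimension standardization: τ is the physical scale of every kernel,
diverged dimensions separate by several τ while non-diverged ones carry
only mutation-scale noise, and inflating the noise dimensions to unit
variance would bury the signal.  The post-merge step encodes the same
fact: families less than τ apart cooperate, compete and intermarry as
one group, so sub-τ cluster splits are not distinct clans.

Relations are read off the cluster centres.  Women of clan X marry men
of the clan whose trait centroid is nearest `p(X)` (X ⇒ Y); the child
of a groom from A and a bride from W carries
`(t1(A), t2(W), p1(A), p2(W))` and is assigned to its nearest centroid.
This yields the father-line map A → child-clan (with W the clan whose
preference centroid is nearest `t(A)`) and the mother-line map
W → child-clan (with the groom clan given by the marriage map).  Cycle
lengths of these functional graphs give the marriage cycle `C_m` and
the descent cycle `C_d = min(father-line cycle, mother-line cycle)` —
clan membership persists along whichever parent line preserves it, so
patrilineal systems (father self-loop) and matrilineal systems (mother
self-loop) both have C_d = 1, while double-descent systems, where
children share no clan with either parent, have C_d = 2.  A
father-line-only definition would misclassify matrilineal direct
exchange (two clans, children in the mother's clan) as C_d = 2.

Taxonomy: (C_m, C_d) = (1,1) with a single clan → clan endogamy; (2,1)
→ dual organization; (≥3,1) → generalized exchange; (2,2) → restricted
exchange; anything else — several endogamous clans, rings with C_m ≥ 3
and C_d ≥ 2, graphs whose nodes reach cycles of different lengths
(flagged inconsistent; the cycle holding the most families is reported)
— is `other`.  The descent *system* is named from centroid spread:
a trait dimension is significant if the centroids span more than
θ·τ (θ = 1 by default); t1 only → patrilineal, t2 only → matrilineal,
both → double, one clan → undivided, several clans with no significant
trait axis → ambiguous.

An independent event-based check (`trace_event_graphs`) rebuilds both
graphs from logged marriages (modal bride-clan → groom-clan and
parent-clan → child-clan relations over the trailing
`event_log_window` steps) instead of centroids.

## Experiments

`run_phase_sweep` repeats the simulation `n_trials` times per (d_c,
d_m) condition (trial seeds = base seed + trial index) and tabulates
structure and descent frequencies; the modal structure per condition is
the phase-diagram value.  Extinct runs count toward the extinction
fraction and win the modal slot only when extinctions outnumber every
lived structure.  The desk-scale default is 20 trials per condition
(full-scale sweeps simply raise `n_trials`); the acceptance script uses
20 seeds per point at the default system size, which one run of
500 steps at N_s = N_f = 50 makes a few-minute computation per point.

Observed behaviour at the four canonical points (b=5, μ=0.1, τ=1,
N=50): (5.0, 0.1) → clan endogamy; (0.3, 0.2) → dual organization;
(0.5, 1.0) → generalized exchange (C_m = 3, patrilineal); (0.2, 1.0) →
a mixture of dual/generalized and longer marriage rings with double
descent.  In this implementation the clean restricted-exchange regime
sits at a somewhat smaller cooperation pressure (d_c ≈ 0.1) than the
fourth canonical point; at (0.2, 1.0) the maternal trait dimension
diverges only intermittently within 500 steps.

## Analytic boundary

Clan endogamy keeps every family kin-and-rival (`friend = rival = 1`);
dual organization halves rivalry but pays a cooperation cost because
mate-clan centres misalign by the mutation scale, shrinking the mate's
cooperation degree by `exp(-α μ²)`, α = O(1).  Weighting each structure
by its sustenance probability (p_C, p_D — user-supplied, or measured by
`estimate_sustenance`, which seeds ideal layouts and counts how often
they persist), dual organization wins when
`d_m/d_c > 1 - exp(-α μ²) + (2/d_c) ln(p_C/p_D)`: a constant ratio at
large d_c and a constant d_m offset at small d_c.  Transitions to
generalized/restricted exchange reuse the template with their own
sustenance probabilities.

## Empirical pipeline

For an SCCS-style table (societies × ordinal variables): z-score each
variable over non-missing entries (population variance; constant
columns dropped), align signs so larger = more pressure, average each
society's available cooperation-mapped variables into `dc_tilde` and
competition-mapped ones into `dm_tilde` (missing cells left out;
pairwise-complete policy), then shift each estimate so its minimum is
zero (only relative magnitudes are identified).  The default mapping
carries ten indicators: social unity and inter-society conflict → d_c;
intra-society conflict and adultery attitudes → d_m, all signs +1.
Variable relevance is ranked by the mean |Spearman ρ| against 0/1 class
codes over all structure-class pairs (ties mid-ranked;
pairs with <3 societies skipped).  Note that with a binary class code
and mid-ranked ties, even a perfectly separating variable caps below
|ρ| = 1; the cap is what perfect separation attains.

## What the synthetic fixtures emulate — and what they don't

`make_clan_cloud` builds ideal clan geometries (isotropic Gaussian
clans, exact preference-on-trait alignment) for each structure; real
simulation end-states have anisotropic, drifting clans, tails feeding
cycles, and occasional sub-τ substructure, so classifier recovery on
fixtures bounds only the well-separated regime (tests use
separation ≥ 5τ, noise ≤ 0.2τ).  `make_sccs_table` draws latent
pressures d_c ~ U(0.2, 5), d_m ~ U(0.05, 3) per society, emits
indicators `sign·loading·latent + Normal(0, noise)` with independent
missingness, and labels structures by thresholding d_m/d_c at
(0.15, 0.5, 1.5) following the theoretical ordering.  It has linear
loadings and independent noise only — no ordinal discretization, no
regional autocorrelation (Galton's problem), no label noise — so
passing recovery tests demonstrates pipeline correctness, not that real
ethnographic coding meets these assumptions.

## Numerical notes

- Marriage weights that underflow to an all-zero row fall back to a
  uniform offer; ties in nearest-centroid assignments break to the
  lowest clan index (determinism).
- The matching loop is compiled (numba) with a pure-Python twin
  (`match_loop_py`) asserted to agree exactly; all stochastic draws
  happen at the numpy `Generator` level in a documented order.
- BIC degenerate cases: duplicate-point clouds get a variance floor of
  1e-12, so the smallest k with zero residual wins.
- `n_steps=0` returns the initial world; a fully extinct world
  classifies as `extinct` and ends the run with outcome "extinct".

## Known limitations

- Patrilineal divergence dominates more strongly than maternal-side
  divergence; restricted exchange therefore occupies a smaller, lower-
  d_c region of the phase plane than the canonical placement, and the
  fourth canonical point lands on a dual/generalized/long-ring mixture.
- Long marriage rings with C_d = 2 (structures outside the four named
  classes) are common near that boundary and are reported as `other`.
- No migration between societies; no ambilineal/bilateral descent; the
  sustenance probabilities entering the analytic boundary are inputs,
  not derived quantities.
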
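# Methods

`presbynet` reimplements, as a tested pipeline, a whole-brain functional
connectome topology analysis for age-related hearing loss (presbycusis)
cohorts: three groups — presbycusis with cognitive decline (PCD),
presbycusis without cognitive decline (PNCD) and healthy controls (HC) —
compared on graph-theoretical properties of resting-state networks built
over the 90-region AAL parcellation.  Because no patient fMRI is
distributable, a synthetic-cohort generator is a first-class part of the
package; this note records the model, the defaults, and what the synthetic
results do and do not establish.

## Analysis model

**Nodes and edges.** Each of the 90 AAL regions is a node.  For a subject
with T×90 ROI signal matrix, the edge weight between regions i and j is
their partial correlation conditioned on the remaining 88 regions, read off
the precision matrix P as −P_ij/√(P_ii P_jj).  Partial rather than marginal
correlation removes indirect dependence mediated by third regions; the
price is a heavy estimation burden (see *Conditioning and rank* below).

**Thresholding.** The weighted matrix is binarized over a sparsity grid
S = 0.06…0.40 in steps of 0.01 (35 levels).  At sparsity S the
round(S·N(N−1)/2) node pairs with the largest |partial correlation| become
edges, so every subject's graph has the same edge count at the same
sparsity, and the series is nested along the grid.  Ties are broken in
(i,j) order with a warning (the weights are continuous, so ties essentially
never occur on real input, but determinism is required for testing).  An
advisory function reports the sparsity at which mean degree equals
2·ln N (≈ 0.101 for N = 90); the conventional grid nevertheless starts at
0.06, and the two conventions are mutually inconsistent — we expose both
and let the grid bounds be plain configuration.

**Metrics.** Global: clustering coefficient Cp, characteristic path length
Lp, global efficiency Eglob, local efficiency Eloc, and the normalized
indices γ = Cp/Cp_rand, λ = Lp/Lp_rand, σ = γ/λ, with Cp_rand, Lp_rand the
means over an ensemble of degree-preserving rewired null graphs
(double-edge swaps, target 10·|E| accepted swaps, proposal cap 100·|E|;
ensemble size configurable, default 100, 20 in the reduced profiles).
Nodal: betweenness centrality (raw Brandes sums over unordered pairs),
degree, nodal efficiency (mean inverse distance to every other node) and
nodal local efficiency (global efficiency of the neighbor-induced subgraph,
index node excluded; including it is available behind a flag).  Every
metric is summarized by its area under the curve (AUC) over the grid,
computed with the composite trapezoid rule — one threshold-independent
number per metric (per node for nodal metrics).

Conventions for disconnected graphs: Lp is the mean over *reachable*
ordered pairs, with the unreachable-pair count reported alongside;
efficiency-type metrics count unreachable pairs as zero contribution.
This keeps all quantities finite at the sparse end of the grid.

**Modularity.** The partition is the fixed six-lobe anatomical grouping of
the AAL90 regions (frontal 6, prefrontal 22, subcortical 22, occipital 14,
parietal 14, temporal 12) — no data-driven community detection.  A
subject's intra-modular strength of module m is the number of edges with
both endpoints in m, averaged over the grid; inter-modular strength counts
edges with exactly one endpoint in m.  Because raw counts scale with module
size (a 6-node module has 15 intra pairs but 504 inter pairs), per-pair
densities are reported alongside; the planted-structure recovery property
(intra denser than inter) holds for densities and cannot hold for raw
counts in small modules.

**Rich club.** Rich nodes are the top 12 % of regions (10 of 90) by nodal
degree averaged over the group's subjects and the full grid; selection is
per group, since hub membership itself reorganizes between groups.  Edges
are classed rich (both endpoints rich), feeder (one), or local (neither);
the three classes partition every edge set, and per-subject class counts
averaged over the grid feed the group comparison.

**Statistics.** Continuous variables pass a per-group Shapiro–Wilk screen
(non-normal if any group p < 0.05), then a one-way ANOVA (normal) or
Kruskal–Wallis (otherwise); categorical tables use Pearson χ² without
continuity correction.  When the omnibus is significant at α = 0.05,
pairwise post-hoc comparisons fit an OLS model
`value ~ group indicator + age + sex + education`, reporting the group
coefficient's t and p; with no covariates this reduces exactly to the
pooled two-sample t-test (verified algebraically in the tests).  Nodal
families are Bonferroni-corrected with m = 90 (nodes per metric per
contrast).  A summary-statistic ANOVA (between/within decomposition from
group means, SDs, ns) lets printed demographic tables serve as worked
examples: the published sex table gives χ² p = 0.776 and the age row
p = 0.321, both reproduced to ±0.005.

## Preprocessing

Applied at the ROI-signal level, in fixed order: discard the first 10
volumes (230 acquired → 220 retained at TR = 2 s); exclude any subject
whose motion trace exceeds 2.0 mm translation or 2.0° rotation in any
direction (strict inequality, matching the "> 2.0" convention); regress an
intercept, the six motion parameters, the global mean (row mean over the
90 ROI columns — the package has no image space, so this is the whole-brain
surrogate) and any supplied white-matter/CSF columns from every ROI signal;
then linearly detrend and bandpass filter 0.01–0.08 Hz.  The filter is an
FFT-domain ideal response with cosine-tapered edges (taper 0.002 Hz):
deterministic and with no filter-order ambiguity.  Detrending precedes
filtering because filtering a ramp through sharp band edges rings.
Constant confound columns are dropped (they carry no signal and would make
the design rank deficient alongside the intercept).

Two numerical consequences deserve emphasis:

**Conditioning and rank.** Global-mean regression makes the 90 columns
exactly collinear (rank 89), and the ideal 0.01–0.08 Hz filter at TR = 2 s,
T = 220 restricts the data to ~66 Fourier degrees of freedom — below the
90 variables.  A fully conditioned partial correlation is therefore
degenerate downstream of these steps.  `partial_correlation_matrix` raises
a conditioning error by default; two escape hatches exist.  Diagonal
loading (`shrinkage`) is the textbook remedy but is *wrong* under exact
collinearity: the null direction dominates the loaded precision and
swamps the partial-correlation ranking (we measured planted-hub recovery
collapsing from 8–10/10 to 0/10).  The Moore–Penrose policy
(`rank_policy="pseudoinverse"`) computes the precision on the span of the
data, preserves the planted ranking through global-mean regression, and is
the pipeline default.  No policy rescues the post-filter rank deficit:
white-spectrum synthetic signals carry information across the whole band,
so the planted-structure analyses (and the reduced-profile pipeline runs
behind them) omit the temporal filter; the filter remains the default for
externally supplied data, whose out-of-band content is noise by
assumption.  This is a genuine limitation of fully conditioned partial
correlation at these acquisition parameters, not an artifact of the
implementation.

**Idempotence.** Detrend and the ideal filter are two non-commuting
projections; re-applying the stage changes generic in-band signals by
~1–3 % through spectral leakage re-entering via the trend fit.  Exact
idempotence (< 1e-6) holds on their joint invariant subspace (flat-band
on-bin spectrum with zero trend fit), which is what the test constructs.

## Synthetic cohorts

The generator emulates 90-ROI cohorts of 230 acquired volumes at TR = 2 s
with the three-group design (default 30/30/50), published demographic
summaries, and planted network structure.  Two constructions are provided.

**Block design** (`plant_covariance`): a block-constant correlation matrix
— `within_module_corr` (default 0.5) inside each anatomical module,
`between_module_corr` (default 0.1) elsewhere — built from a latent factor
model (one global factor, one factor per module, optional cross-module hub
loadings), so it is positive definite by construction and exactly
block-constant without hubs.  Dense within-module blocks survive partial
correlation as dense positive within-module partial correlations, giving
thresholded graphs lattice-like clustering with noise-edge shortcuts:
γ > 1, λ ≈ 1, σ > 1 across the whole grid, and the canonical monotone
trends (Cp, Eloc, Eglob rising with sparsity; Lp, γ, σ falling; λ ≈ 1
with a weak decline).  This is the structure used for the small-world and
grid-trend checks.

**Modular small-world graphical model** (`plant_ggm_covariance`): the
structure is specified directly in partial-correlation space, because that
is what the pipeline estimates.  Design: within-module ring lattices
(degree 4 at partial correlation 0.10), ten hub regions (the top-degree
regions of the healthy-control group-average network: bilateral
supplementary motor area, precuneus, paracentral lobule, middle temporal
gyrus, right superior temporal gyrus, left middle occipital gyrus) carrying
ten cross-module partner links plus a four-neighbor hub ring at partial
correlation 0.12 and no within-module links, and a global shared component
(marginal correlation 0.1) mixed into the covariance and removed downstream
by global-mean regression.  The target precision I − P must be positive
definite (checked; a definiteness error names the smallest eigenvalue).

This design was not the first choice; it is what measurement forced.  Two
natural alternatives fail against the pipeline itself: (i) the shared
between-module correlation of a block design is conditioned away by
partial correlation, so scaling it between groups changes the binarized
graphs not at all; and (ii) no positive-definite covariance-level hub
enrichment can place 10 hubs at the top of group-average degree when
dense 22-node modules saturate within-module partial mass (each row's
total absolute partial correlation is spectrally capped near 1).  Sparse
within-module lattices spend that budget on few strong, detectable links
and leave room for hub stars — a planted structure the estimator can
actually recover: with study-sized groups (n = 30) the selected rich club
recovers ≥ 8 of the 10 planted hubs in every tested cohort.

**Group effects** are multiplicative scales on the two link families:
`within_scale` (segregation) and `hub_scale` (integration).  The patient
preset (PCD: within ×2.2, hubs ×0.2; PNCD: ×1.6, ×0.6) raises clustering
and path length and lowers global efficiency — the reported effect
directions.  No effect sizes are published for any network metric, so the
magnitudes are free parameters of the generator, chosen so that the planted
Lp direction is recoverable at the prescribed simulation scale (10
subjects per group, 20 replicates); measured subject-level effect sizes at
the preset are roughly +1.9 SD (Cp AUC), +0.74 SD (Lp AUC), −0.41 SD
(Eglob AUC).

**Demographics** are truncated-normal at the published group means/SDs
(ages ≥ 60 for patients, education ≥ 8 years), with pure-tone averages
truncated at the 25 dB diagnostic boundary (patients above, controls
below) and MoCA truncated at the 26-point boundary (PCD below, others at
or above), so the clinical grouping rules reproduce the configured group
sizes exactly.  Sex is assigned to exactly match the published male/female
counts (14/16, 12/18, 24/26), making the χ² worked example deterministic.
Motion traces are bounded random walks kept strictly below the exclusion
limits, with a single super-threshold excursion injected for subjects
configured to be excluded.

**What the generator does not emulate:** image-space artifacts (spikes,
drift fields, spatial smoothness), temporal autocorrelation (samples are
independent in time, so the 0.01–0.08 Hz filter only removes information —
see above), region-size heterogeneity in signal quality, and any coupling
between demographics and network structure.  Passing tests on synthetic
cohorts therefore establish that the pipeline recovers structure *of the
planted kind at the planted strength*; they do not certify sensitivity on
real BOLD data.

## Determinism and numerics

Every source of randomness descends from a single integer seed through
`numpy.random.SeedSequence` spawning (per-group demographic streams,
per-subject time-series and motion streams, per-graph null-ensemble
streams).  Degree-preserving rewiring pre-draws all proposals from the
numpy generator and runs the rejection loop in a numba kernel, so results
are bit-identical across runs and independent of the compiled backend.
Shortest paths use `scipy.sparse.csgraph`; triangle counts use dense
matrix products (N = 90); betweenness uses the Brandes algorithm
(networkx).  Brute-force BFS/enumeration oracles for every metric live in
the test suite and agree with the implementation to 1e-10 on random graphs
with N ≤ 10.

Problem sizes in the standard verification profiles: small-world and
trend checks use 6-subject cohorts with 20-null ensembles; parameter
recovery uses 20 replicate cohorts of 10 subjects per group; null
calibration uses 200 replicate cohorts of 10 per group (clustering AUC
omnibus rate checked against the binomial 95 % band around 0.05, and
Bonferroni-corrected nodal degree tests checked to flag ≤ 5 %).  These
sizes were chosen to make the statistical claims testable at desk scale;
the library itself handles the full 30/30/50 design.

## Known limitations

- Real 0.01–0.08 Hz-filtered data at T = 220 cannot support a fully
  conditioned 90-region partial correlation (rank ~66 < 90); the
  pseudoinverse policy measures partial structure on the data's span, and
  group comparisons remain valid because the restriction is identical
  across groups, but absolute partial-correlation values are not
  comparable with full-rank estimates.
- The λ (normalized path length) curve is statistically flat (≈ 1) at
  these network sizes; its downward trend is weak and only its sign is
  asserted.
- Bonferroni correction with m = 90 per metric per contrast is
  conservative; no FDR alternative is wired into the default flow.
- The paper-gap choices (null-ensemble size, AUC quadrature, tie-breaking,
  nodal Bonferroni family, Kruskal–Wallis as the non-parametric omnibus,
  pooled-variance post-hoc t) are documented at their definitions and in
  this note; all are configurable where a practitioner might disagree.
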
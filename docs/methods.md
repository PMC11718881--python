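# Methods

This note documents the statistical procedures implemented in `herdnet`,
the default parameters and why they hold their values, what the synthetic
generator does and does not emulate, and the numerical choices made where
the methods literature leaves room.

## Data model

The observational unit is the 10-minute instantaneous scan sample: one
record per visible individual (behavioural category from a six-category
ethogram — foraging, rest, locomotion, social, vigilance, other — plus a
finer activity pattern and an optional zone), together with the set of
unordered proximity pairs observed within one body length. Social
interactions are a separate all-occurrence event stream of directed,
timestamped events (affiliative, or agonistic with an offensive/defensive
role class). Observation effort is a per-day set of non-overlapping
windows whose lengths sum to the contact hours used as the denominator of
all rates.

Partial visibility is allowed: a scan may cover any subset of individuals,
and every dyadic denominator is the count of scans where **both** members
have records. Under the full-visibility protocol the fixtures come from,
this coincides with the total scan count.

## Association

Spatial groups at a scan are the connected components of the
proximity-pair graph (gambit of the group with transitive chaining, the
standard field rule: if A is within range of B and B of C, all three are
one group). `AI_ij` is the proportion of jointly observed scans in which
the dyad shared a group; dyads never jointly observed get AI 0 and an
explicit flag. Interaction rates are event counts per contact hour per
ordered dyad; a dyad with no events has rate 0, not missing.

## Data-stream permutations

The null model permutes group membership in the data stream itself
(Bejder-style), so group sizes at every scan and each individual's number
of observations per day are conserved. One step:

1. pick a day uniformly among days with at least two recorded groups;
2. pick two distinct groups on that day and one member of each;
3. swap the two individuals unless the move would place an individual
   twice in one scan (rejection sampling, capped at 1000 attempts; a
   dataset with no legal swap raises a degeneracy error).

The chain is **cumulative** with the statistic recorded after every swap
and no burn-in discarded; the permutation count (default 1000) is the
chain length. The empirical p-value is the plain proportion of post-swap
statistics at least as extreme as the observed one. Calibration on
exchangeable synthetic data (200 replicates, nine individuals, 60 scans)
showed the CV test's positive rate at nominal 5% and its p-values
indistinguishable from uniform at chain length 1000, while much shorter
chains (200 swaps) were anticonservative (~10% positives) because the
chain has not moved far from the observed configuration. Chain length
should therefore not be cut below the default. The scheme and chain
length are recorded in every report for auditability.

Non-randomness uses the coefficient of variation of the dyadic values
(sample sd over mean, upper triangle for symmetric matrices, all ordered
pairs for directed). Dyad-level classification uses the same chain: for
each dyad, `p_high` is the share of permuted AI values at least the
observed one; *preferred* means `p_high ≤ 0.05` and *avoided*
`p_high ≥ 0.95` — one tail read at both ends.

## Mantel tests

Matrix association between two symmetric dyadic matrices is the Pearson
correlation of paired upper-triangle entries, with simultaneous
row/column permutation of the second matrix (sampled, or exhaustive over
all node permutations via `exact=True` for small groups). Directed
matrices must be symmetrized first by summing the two directions, the
convention matching vegan-style Mantel inputs.

A note on the packaged worked example: the published correlation between
the association and synchrony matrices is 0.703, but the Pearson Mantel
statistic computed from the *printed, rounded* matrices is 0.846 (Spearman
0.930). No method variant we tried reproduces 0.703 from the printed
values, so the published figure was presumably computed on unrounded or
per-activity matrices that were not released. The package keeps the
printed matrices as fixtures of record and reports what they actually
give; the qualitative conclusion (strong positive association-synchrony
correlation, p < 0.01) is unaffected.

## Node measures, communities, assortment

Weighted degree follows the tnet `degree_w` convention,
`WD = k^(1-α) · S^α` with `k` the number of nonzero ties and `S` their
summed weight. α defaults to 0.5, the value under which the packaged
per-individual measures are internally consistent (e.g. √(1 × 0.665) =
0.815 for the focal pair's association column). For **directed** matrices
both `k` and `S` are taken over *outgoing* ties — the published measures
fix this convention unambiguously (an individual with only incoming
interactions has WD 0 despite positive total strength, and the
out-tie form reproduces every printed value to rounding), while total
(in+out) strength is reported separately as `S`.

Community detection is igraph's multilevel (Louvain) modularity
optimization on the symmetrized matrix, restarted over 100 random vertex
orders with the best-modularity partition kept; given the seed the
restart schedule, and hence the result, is deterministic. Modularity is
computed by our own weighted Newman–Girvan implementation (cross-checked
against igraph's in the tests).

The significance of detected structure is assessed by shuffling the
multiset of dyadic weights across dyad slots, re-running detection, and
comparing best modularities. Relabelling nodes would leave the graph
isomorphic (and the best Q identical), so weight-multiset shuffling is
the weakest exchangeability assumption that actually destroys community
alignment while preserving the weight distribution.

Continuous-trait assortment is the edge-weighted Pearson correlation of
trait values across edge endpoints (both orientations of each undirected
edge), i.e. the `assortment.continuous` estimator; significance comes
from node-label permutations of the trait. The coefficient is invariant
to affine transformations of the trait.

## Dominance

Winner attribution: offensive initiators win; the direction of defensive
(submissive) events is reversed so the recipient of submission wins.
David's scores use raw win proportions `P_ij` (a no-encounter dyad
contributes 0 to both sides, not the chance-corrected Dij variant): with
`w_i = Σ_j P_ij`, `w2_i = Σ_j P_ij w_j` and the loss-side analogues,
`DS_i = w_i + w2_i − l_i − l2_i`. The sum over individuals is zero by an
algebraic identity, which the published dominance-index column satisfies
exactly.

Linearity: Landau's `h = 12/(N³−N) Σ_i (V_i − (N−1)/2)²` from dominance
out-degrees, with every unknown or tied dyad assigned a random direction
in each of `n_rand` randomizations; h′ is the mean, and the p-value is
the right-tail proportion of h under fully random dominance matrices.
With all dyads decided h′ reduces to plain h.

## Behavioural synchrony

`BSI_ij` is the share of joint scans with the same behavioural category
(or activity pattern at the finer level). The per-behaviour variant for
behaviour *b* uses a Jaccard-style denominator — joint scans where both
show *b* over joint scans where at least one does — which keeps values in
[0, 1] and equal to 0 when the behaviour is absent from the dyad.

The randomization null picks one individual uniformly per permutation,
selects 100 of its scans (all of them if it has fewer) and permutes the
behaviour labels among them, preserving the individual's marginal
behaviour distribution while destroying temporal alignment. Two
read-outs:

- the **group mean** BSI is compared against all permutations;
- each **dyad's** p-value is computed over the permutations whose
  shuffled individual belongs to that dyad. Permutations that shuffle a
  third individual leave the dyad's BSI bit-identical and carry no
  information about it; counting them (as a literal reading of the
  proportion-greater rule would) makes the per-dyad test either
  never-significant or wildly anticonservative depending on how ties are
  broken. Conditioning on the involved permutations restores nominal
  behaviour (measured 4.1% significant dyads at the 5% level on
  exchangeable data, slightly conservative because of ties in the
  discrete BSI).

Cluster contrasts compare mean BSI over within-cluster vs between-cluster
dyads, with a cluster-label permutation p-value; a partition without both
kinds of dyads is rejected.

## Space and time

Time budgets are per-individual proportions of scans per behaviour per
time-of-day bin (defaults: morning 05:00–10:00, afternoon 10:10–15:00,
evening 15:10–20:30); scans outside every bin land in an explicit
`unbinned` bucket. Zone use is scored against availability: electivity is
Ivlev's `(o − e)/(o + e)` with the expected share proportional to zone
area (degrading gracefully to equal shares for equal quadrats), and
evenness is Dickens' spread of participation index — both chosen because
they have exactly the documented endpoints (−1 unused zone; SPI 0 for
uniform use, 1 for single-zone use). When a secondary enclosure is
closed partway through a study, the dataset splits at the cutover date
and the availability set (and hence expectations) is recomputed per
period. A tidy per-scan table (individual, cluster, bin, period,
behaviour, hay-zone flag) is exported for external mixed-model tools;
the regressions themselves are out of scope.

## Kinship

Standard recursive kinship with founders pairwise unrelated and
non-inbred: `φ(i,i) = (1 + φ(sire_i, dam_i))/2`, and for i not an
ancestor of j, `φ(i,j) = (φ(sire_i, j) + φ(dam_i, j))/2` with missing
parents contributing zero (evaluation in topological order guarantees the
ancestor condition). A vectorized gene-dropping Monte Carlo (unique
founder alleles, random transmission, IBD probability across sampled
alleles) serves as an independent oracle; the two agree to 0.01 at 10⁵
drops. The packaged pedigree is one generation deep with grandparents
treated as founders, enough to pin the full-sib (0.25), half-sib (0.125)
and parent-offspring (0.25) benchmarks.

## Synthetic generator

The generator emulates the study design the package targets: N individuals in
planted clusters observed by 10-minute scans over several weeks, with an
event stream in parallel. Defaults are the study conditions: 9
individuals in clusters of 3/4/2; 25 days × 16 scans (≈ 65 contact
hours); behaviour-category base rates matching the published time budget
(0.565 foraging, 0.199 rest, 0.090 locomotion, 0.025 social, 0.105
vigilance, 0.016 other); within/between per-scan association
probabilities 0.6/0.05; synchrony coupling 0.45 (chosen so that the
expected within-cluster agreement `c² + (1−c²)Σ p_b² ≈ 0.5` and the
independent-pair agreement `Σ p_b² ≈ 0.38` bracket the published dyadic
synchrony values); affiliative rates 0.5/0.02 events per dyad-hour
within/between clusters; agonistic events at 0.04 per dyad-hour with the
higher-ranked individual of a fixed linear order winning with
probability 0.9 and 60% of bouts recorded as submissive.

Mechanisms: each cluster draws a latent behaviour state per scan and each
member copies it with probability `sync_coupling`, else draws
independently — the simplest generative story for cluster-level
synchrony. Proximity pairs are independent Bernoulli draws per dyad per
scan; chaining is applied downstream by the association module, exactly
as in the field protocol. One consequence worth knowing: with 26
between-cluster dyads at p = 0.05, some between-cluster edge exists in
most scans, so chaining merges clusters often and the *realized*
between-cluster AI (≈ 0.4) sits far above the pairwise probability. The
within−between contrast, community recovery (ARI = 1 in 20/20 seeds at
the default structure), and test calibration are unaffected, but the
generator's absolute AI level is higher than in the sparse field data it
emulates. Zones are drawn per member from cluster-specific preference
distributions over the default 22-quadrat map (two enclosures, hay in
eight quadrats, water in one).

The generator does **not** emulate: spatially explicit movement or
autocorrelated trajectories, temporal autocorrelation of behaviour beyond
the per-scan latent state, observer-missed scans clustered in time,
weather covariates, or interspecific interactions. Passing tests
therefore validate the estimators under exchangeable-scan assumptions,
not robustness to temporally structured noise.

The `null_dataset` variant (equal association probabilities, zero
coupling) produces exchangeable individuals and is the basis of all
calibration experiments: 200 replicates of 60-scan datasets, 1000-swap
chains for the association tests and 300 shuffles for the synchrony null
— sizes at which the Monte Carlo error of a 5% rate over 200 replicates
(±3 percentage points at 95%) matches the granularity of the assertions.

## Numerical choices and degenerate inputs

- Empirical p-values are plain proportions of the null at least as
  extreme as the observed value (ties count as extreme, with a 1e-12
  float guard); no +1 smoothing.
- Matrices are validated on construction: symmetric unless declared
  directed, diagonal forced to zero, labels unique.
- CV of an all-zero matrix, modularity of a zero-weight graph, SPI with
  fewer than two available zones, and assortment of a constant trait all
  raise rather than return NaN.
- The community-detection seed drives both the restart order and
  igraph's internal RNG, making results reproducible bit-for-bit.
- Master seed → per-stage substreams: the pipeline derives independent
  seeds per stage from a stable string hash, so adding a stage never
  perturbs another stage's results.

## Limitations

- The agonistic record behind the published dominance indices was not
  released, so David's score magnitudes can be validated only through
  identities (sum to zero) and synthetic recovery, not against the
  printed column.
- The published per-activity synchrony table and the unrounded matrices
  are unavailable; per-activity BSI denominators are therefore a
  documented convention, and the association-synchrony Mantel value is
  reproducible only up to the discrepancy described above.
- Cumulative swap chains make successive null statistics autocorrelated;
  p-values are calibrated at the default chain length but the effective
  sample size of the null is smaller than the permutation count.
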
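# Methods

`mitopop` implements the classical single-locus phylogeographic workflow for
short mtDNA fragments: a population sample of aligned sequences is collapsed
into haplotypes, within- and between-group variability is summarised,
geographic structure is tested by variance partitioning and permutation, the
genealogical signal is visualised as a statistical-parsimony network, the
demographic history is probed through neutrality statistics and mismatch
distributions, and ancestral geographic ranges are reconstructed on supplied
trees by dispersal–vicariance parsimony.  This note records the models, the
parameter conventions, the numerical choices, and what the synthetic data do
and do not establish.

## Data model and site filtering

All statistics operate on one fixed "analyzable" site set: any column
containing a gap (`-`) or ambiguity (`N`) in **any** sequence is excluded
everywhere (complete deletion).  This mirrors the common practice of trimming
an alignment to a fixed fragment before analysis, and it guarantees that
`K = pi * L` holds exactly with a single length `L`.  Haplotypes are defined
by exact sequence identity over the full alignment; identifiers `H1, H2, ...`
are assigned in descending order of total count with ties broken by first
occurrence, because published haplotype labels are generally not derivable
from the sequences alone.

## Diversity statistics

* Haplotype (gene) diversity uses the unbiased estimator
  `h = n(1 - Σ p_i²)/(n - 1)` with Nei's (1987, eq. 8.12) sampling variance.
* Nucleotide diversity is the mean raw pairwise mismatch count `K` over all
  individual pairs (haplotypes weighted by counts), divided by `L`.  Distances
  are uncorrected: the low divergences typical of intraspecific mtDNA make
  model corrections negligible, and reported tables in this field are
  conventionally uncorrected averages.  The standard deviation of `pi` is the
  Nei (1987, eq. 10.7) stochastic variance, which includes both sampling and
  evolutionary components; a pure sampling variance would be smaller.
* A site is parsimony-informative when at least two states each occur in at
  least two sequences; variable sites failing that are singletons.
* Monomorphic groups report `h = pi = K = 0`; single-individual groups are
  flagged undefined rather than dropped.

Because the unbiased corrections depend on `n`, pooling two identical
populations changes `h`, `pi` and `K` only through `O(1/n)` correction terms;
the tests assert equality at that tolerance, not exactly.

## Rarefaction comparison of regional diversification

To compare regions of unequal size, each region is repeatedly subsampled to a
common `n` (default: the smallest region) without replacement, independently
per region, and seven indices are computed per draw: `h`, `pi`, `K`,
haplotypic richness `Hapr`, private haplotypes `Np`, `Np/N` and `Np/Hapr`.
Privacy is classified on the pooled replicate — a haplotype is private to a
region iff it appears in that region's subsample and in no other region's
subsample of the same draw — so `Np` depends on the joint draw, matching the
"pooled dataset" convention rather than privacy relative to the full sample.
Region pairs are compared per index with Student's pooled-variance unpaired
t-test (a `welch=True` switch is provided).  These replicate vectors are
pseudo-replicates of one dataset: the P-values measure the stability of the
subsampling, not independent sampling from the populations, and should be
read as descriptive.  The Monte-Carlo mean of `Hapr` is validated against
Hurlbert's closed-form hypergeometric expectation.

Subsampling RNG substreams are keyed by `(seed, replicate, region)` so the
result is independent of evaluation order.

## Distances, AMOVA and differentiation coefficients

Nucleotide divergence between haplotypes uses the Tajima–Nei (1984)
correction with base frequencies pooled over the pair; it reduces to
Jukes–Cantor under equal composition and raises a saturation error naming the
offending pair when `1 - p/b <= 0`.

AMOVA follows Excoffier, Smouse & Quattro (1992): sums of squares are built
from squared inter-individual distances, where the supplied molecular
distance matrix is taken as already representing the squared-distance entries
(the haplotype-identity metric `d = 1 - δ` is its own square).  Variance
components come from the expected mean squares with the standard unequal-n
coefficients; fixation indices are component ratios and are reported as
computed (negative estimates are not clamped).  Permutation schemes match the
tested null: individuals among populations (Φ_ST/F_ST), individuals among
populations within groups (Φ_SC), whole populations among groups (Φ_CT).
P-values use the `(b + 1)/(B + 1)` estimator with `>=`-observed tie handling,
so `P` is never zero.  Pairwise population structure runs a one-level AMOVA
per pair under both metrics, with significance after multiple testing decided
by the Benjamini–Yekutieli critical value `alpha / Σ_{i<=m} 1/i`, which is
valid under arbitrary dependence among the pairwise tests.

`GST`/`NST` use the Pons & Petit (1996) framework with harmonic-mean
small-sample corrections and equal population weights; `NST` replaces the
identity metric by molecular distances, and `NST > GST` is tested by
permuting haplotype identities on the distance matrix (1000 permutations by
default), which preserves all frequencies while breaking the
genealogy–geography association.

## Statistical-parsimony network

The connection limit is the largest number of steps `j` whose "probability of
parsimony" stays above the confidence level (default 0.95).  That probability
is computed from a Poisson substitution model: with per-site divergence `d`
obtained by Jukes–Cantor correction of `p = j/L`, parsimony requires every
observed difference to be a single substitution and every identical site to
have experienced none, giving
`P(j) = [d e^{-d} / p_vis]^j [e^{-d} / (1 - p_vis)]^{L-j}` with
`p_vis = (3/4)(1 - e^{-4d/3})`.  This is a deliberately transparent stand-in
for the original restriction-data derivation; it preserves the properties
that matter (certainty at `j = 0`, monotone decline in `j`, limit growing
with `L`, a 95% limit of several steps at a few hundred bp).  Single-step
connections are always allowed.

The network is built agglomeratively in increasing mutational distance (raw
mismatch counts, as in TCS): all one-step pairs are linked (which exposes
homoplasy loops), multi-step pairs join only previously disconnected
components, inserting inferred intermediate haplotypes whose sequences are
imputed by switching the differing sites one at a time in ascending position
from the more frequent endpoint.  Ties are broken by joint haplotype
frequency, then current degree (interiority), then haplotype id, and
components farther apart than the limit remain separate.  Candidate ancestral
haplotypes are ranked by `count * (1 + degree)` normalised per component — a
frequency-plus-interiority weight in the spirit of outgroup probabilities,
not the exact Castelloe–Templeton computation.

## Neutrality tests and their null

Tajima's `D` uses the standard `a1 ... e2` coefficients; Fu's `Fs` evaluates
`S' = P(#alleles >= k_obs | theta = K)` under the Ewens sampling formula with
exact (arbitrary-precision) unsigned Stirling numbers, using the pi-based
theta as in the original definition; `R2` uses the folded singleton spectrum
(no outgroup).  Monomorphic groups render these as undefined.

Significance comes from neutral constant-size coalescent simulation
conditioned on the sample size and on the observed number of segregating
sites: each null replicate draws a genealogy and places exactly `S` mutations
on branches chosen proportionally to length (the fixed-`S` conditioning of
Hudson).  This calibrates the lower-tail test of `D` to its nominal level,
whereas simulating with Watterson's theta unconditionally is measurably
anticonservative (we observed ~7.6% rejections at nominal 5% in 500 neutral
replicates, against ~5% under fixed-`S`).  All three statistics use lower-tail
P-values (`(b+1)/(B+1)`), the direction in which expansions push them.  The
conventional significance level for `Fs` is 0.02 rather than 0.05; the raw
P-value is reported and the threshold left to the caller.

## Mismatch distributions and expansion models

The observed mismatch distribution is the normalised histogram of pairwise
difference counts; its mean equals `K` identically.  Harpending's raggedness
is `rg = Σ (x_i - x_{i-1})²` including the step down to zero past the last
class.

Expected spectra are derived from the pairwise coalescent in mutational time
units (`tau = 2 u t`; the expected differences for a pair coalescing at `t`
is `t`):

* **Sudden demographic expansion** — hazard `1/theta1` until `tau`, then
  `1/theta0`.  The spectrum is the stationary geometric of `theta1` weighted
  by the probability of recent coalescence, plus
  `e^{-tau/theta1} * (Poisson(tau) ⊛ geometric(theta0))` — Li's shifted form,
  evaluated through incomplete-gamma functions and a Poisson convolution,
  which is numerically stable for `theta0 -> 0` (where it tends to the pure
  Poisson wave).
* **Spatial expansion** — two lineages sampled in one deme of size `theta`
  either coalesce there (rate `1/theta`) or separate (rate `2M/theta`);
  separated lineages never meet again among effectively infinite demes and
  coalesce only in the single ancestral deme (size `theta`) entered at `tau`.
  Published variants of this model differ in the ancestral-size convention;
  the one-`theta` parameterisation is used here and the goodness-of-fit
  surface (SSD) is the quantity of record, not the individual parameters.

Parameters minimise the SSD between observed and expected spectra over the
observed difference classes (Nelder–Mead, non-negativity enforced, three
random restarts plus a deterministic start at `tau = K`; `theta1` capped at
1e5 and the spatial `M` at 50, beyond which the island model is numerically
panmictic and the likelihood surface is a ridge).  `P_SSD` and `P_rg` come
from a parametric bootstrap: datasets of the same size are simulated with
msprime under the fitted parameters, re-fitted (single start at the fitted
values), and `P = (#{SSD_sim >= SSD_obs} + 1)/(B + 1)`; the expansion model
is conventionally accepted when `P_SSD > 0.05`.  The bootstrap, not a label
permutation, is the resampling scheme appropriate to a goodness-of-fit SSD.

## Dispersal–vicariance reconstruction

Ancestral ranges over areas `{A, B}` (with the composite `AB`) are optimised
under the Ronquist (1997) cost regime: vicariant splitting of a widespread
range and within-area speciation are free; each dispersal (area gained) and
extinction (area lost) on a daughter lineage costs one.  A Sankoff-style
inside pass over the three candidate ranges yields minimal subtree costs and
exact counts of co-optimal sub-reconstructions; an outside pass completes
exact per-node marginal range frequencies and expected per-node event counts,
with co-optimal reconstructions weighted uniformly (the S-DIVA convention).
Across a tree sample, nodes are matched by clade tip set on a reference
topology and frequencies averaged over the trees containing the clade.  Trees
are inputs — from any source, including the simulator's true genealogies —
and no tree inference is performed here.

## Coalescent simulator

`simulate` wraps msprime (haploid samples, `ploidy = 1`) with all observables
parameterised by `theta` (per-locus `2Nu`, the expected pairwise difference
of a constant-size sample) and event times in mutational units.  Mutations
default to finite-sites Jukes–Cantor on the 453-bp fragment so that distance
corrections and network homoplasy are genuinely exercised; an infinite-sites
mode maps each mutation to its own column for closed-form checks.  Genealogy
and mutation processes use independent seeds derived from one
`SeedSequence`: msprime couples the two when given the same seed, which we
measured as a ~5% upward bias in `E[S]` and `E[K]`.

The study-shaped fixture emulates the analysed system: 155 samples in 15
populations (sized 18/17/7 | 3/10/8/11/10/3 | 12/7/16/8/11/14) nested in an
East Atlantic region and a two-basin Mediterranean.  Its history is a
two-deme vicariance at `tau = 2.5` with secondary contact at `tau = 0.5`
(scaled migrant number 1000, effectively remixing the demes) and a 2000-fold
post-contact expansion to a present per-deme `theta = 200`.  These values
were chosen from pairwise-coalescent expectations so that, on average,
`K ~ 1.6` (`pi ~ 0.0035`), `S` and the haplotype number are a few tens, two
shallow haplogroups sit a few mutational steps apart, and Tajima's `D` is
clearly negative — the qualitative regime of a low-diversity mtDNA fragment
after glacial vicariance and postglacial expansion.  Single realizations
scatter widely around these expectations (a handful of deep-branch mutations
shifts `K` by a factor of two in either direction); that scatter is genuine
coalescent variance, and no seed was selected for its output.

What passing tests on this fixture show: the estimators, permutation schemes
and fits behave correctly on data with realistic statistical structure.  What
they do not show: robustness to alignment error, sequencing artefacts,
selection, or recombination — none of which the generator emulates.

## Problem sizes used by the checks

The test suite and acceptance script scale their Monte-Carlo work to what a
single CPU handles comfortably: simulator calibration uses 10,000 replicates
at `n = 10`; the type-I calibration of Tajima's `D` uses 500 neutral datasets
(`n = 30`) with 99 fixed-`S` null simulations each; expansion-parameter
recovery uses 50 replicates at `n = 100`; AMOVA and DIVA are checked against
exhaustive oracles on instances small enough to enumerate (<= 30 individuals,
<= 5 tips).  Pipeline defaults (10,000 permutations in the field's
convention) remain available through configuration.

## Known limitations

* The parsimony-probability model is an approximation; its limits are of the
  right order (6 steps at 453 bp / 95%) but are not bit-identical to TCS.
* The spatial-expansion bootstrap simulates 30 demes as a stand-in for the
  infinite-island assumption of the closed form.
* `GST`/`NST` weight populations equally; very small populations (n < 2) are
  dropped from those estimators.
* Ambiguity resolution in network construction is deterministic but
  heuristic; alternative equally-parsimonious connections are not enumerated.
* The rarefaction t-tests inherit the pseudo-replication caveat above.
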
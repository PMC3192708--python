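# Methods

This note documents the models implemented in `cytodiscord`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
data can and cannot establish.

## Net sites (complete deletion)

Every statistic is computed on the columns free of gaps (`-`) and missing
data (`N`) in **all** sequences under analysis. The mask is recomputed per
analysis set: a subgroup can therefore have more net sites than the full
alignment (its gap-bearing individuals may be absent). This matches the
behaviour of standard polymorphism software, where per-group "(net)" site
counts differ across rows of the same locus table. Consequence: haplotype
counting and segregating-site counting also operate on net sites, so two
sequences differing only inside masked columns collapse to one haplotype.

## Summary statistics and neutrality tests

* **π and k.** k is the exact mean over all unordered pairs of per-pair
  difference counts, computed per column from allele counts
  (pairs − Σ<sub>a</sub> C(c<sub>a</sub>,2)); π% = 100·k/L<sub>net</sub>.
* **Watterson's θ** uses the segregating-site count S, not the total
  mutation count η; on data with more than two alleles per site the two
  differ, and published table cells computed from η will not be matched
  by design.
* **Tajima's D** follows the 1989 variance coefficients exactly
  (a₁,a₂,b₁,b₂,c₁,c₂,e₁,e₂). Undefined (NaN) when S = 0 — never coerced
  to zero.
* **Fu's Fs** is computed from (n, H, k) alone: θ̂ = k, S′ = P(K ≥ H)
  under the Ewens sampling formula. Unsigned Stirling numbers of the
  first kind are generated by the row recurrence in log space
  (logaddexp), exact to machine precision for n ≈ 100 with no overflow.
  S′ saturating to 0 or 1 yields a signed-infinity marker with a warning.
* **R2** uses the folded singleton definition (minor-allele count 1):
  no outgroup polarization is attempted anywhere in the package.
* **Coalescent-null p-values** condition on the observed S: each of the
  `reps` replicates draws a constant-size Kingman genealogy and places
  exactly S mutations uniformly on total branch length (infinite sites),
  then recomputes the statistic. Tails: two-tailed for D (2·min of the
  two one-sided empirical probabilities, +1-corrected), lower-tailed for
  Fs and R2. Whether the original analyses conditioned on S or on θ is
  not documented; conditioning on S avoids a nuisance parameter.

## Recombination tests

* **Rm** (four-gamete): biallelic segregating sites only; >2-allele sites
  are skipped with a warning. Incompatible site pairs define open
  intervals; Rm is the maximum number of pairwise-disjoint intervals via
  the greedy right-endpoint scan, which is optimal for interval packing.
* **PHI (Φw)**: restricted to biallelic parsimony-informative sites,
  where the refined incompatibility score of the original statistic
  reduces to the binary four-gamete test. Multi-allelic sites are rare in
  intron/cyt b data at these divergences and are skipped with a warning.
  Φw is the mean incompatibility over pairs of informative sites within a
  rank-distance window (default 100 informative sites); the permutation
  p-value is (#{perm Φ ≤ Φ_obs}+1)/(perms+1). Note that when the number
  of informative sites does not exceed the window, Φ is permutation
  invariant and p = 1; the test has power only through the windowing.

## Divergence

D<sub>xy</sub> is the mean between-group pairwise difference per net site
of the **union** mask of the two groups; the within-group π entering
D<sub>a</sub> is recomputed on that same mask for internal consistency.
Site classes: *fixed* (no shared allele between groups), *exclusive*
(polymorphic in exactly one group), *shared* (polymorphic in both). The
published table's ψ columns are interpreted as fixed/exclusive/shared
counts; since that mapping is not defined in the source table, those cells
are not used as numerical anchors.

## The structured coalescent and sequence evolution

Demes carry **haploid** effective sizes (gene copies): coalescence rate
k(k−1)/(2N) per generation among k lineages in a deme of size N, in the
continuous-time approximation (valid for N ≫ k; all scenario sizes are
≥ 10³ × sample size). Merge events move surviving lineages into a
destination deme with its own size; no migration, growth, or within-locus
recombination. The packaged `rhinella_mtdna` scenario uses the printed
haploid sizes directly (69k/190k/143k, ancestors 63k/103k); between the
two events the merged LAB+RAB deme takes the 63k ancestral size, the
event-wise reading of the history. Generation time is fixed at 1 year.

Mutation is event-based finite-sites: root sequence from the base
frequencies (uniform by default), Poisson(μ·L·branch length) substitutions
per branch, uniform target site, transition with probability
`ts_proportion` (default 0.9 for mtDNA, where strong transition bias is
typical for vertebrate cyt b; the empirically fitted value was not
published), else an equiprobable transversion. Multiple hits are allowed;
no rate-matrix exponentiation is performed because the bootstrap needs
pattern realism, not likelihood evaluation. μ = 0.69×10⁻⁸/site/year for
cyt b — the only dimensionally consistent reading of the published
"1.38% per Myr" between-lineage divergence rate — and 2.01×10⁻⁹ for
nuclear introns.

## Tree reconstruction and the ILS test

Trees are reconstructed by neighbor joining on Kimura two-parameter
distances (P, Q over pairwise-complete sites; saturated pairs capped at
distance 5 with a warning). Ties in the Q-criterion break to the lowest
index pair; negative branch lengths are floored at zero with the excess
moved to the sister branch, preserving path lengths. At the 1–3%
divergences relevant here the monophyly call is signal-limited, not
estimator-limited, which makes 10⁴ replicates desk-scale; an external
(e.g. ML) tree can be injected per replicate via `tree_from_newick`.

Monophyly is an unrooted-bipartition property: a tip set is monophyletic
iff some edge splits it exactly from the rest (no outgroup is simulated,
so no rooting is defensible). In the bootstrap, a bipartition carried by a
**zero-length** edge counts as non-monophyletic: with no informative
variation the resolution would be an arbitrary tie-break, and counting it
against monophyly is conservative toward the ILS null. Replicates with no
variation at all are counted as non-monophyletic and reported in
`n_degenerate`. The test rejects ILS when non-monophyly of the focal
group occurs in less than `threshold_pct` (default 5%) of replicates.
Default 10,000 replicates; the bundled acceptance script uses 1000, which
bounds the Monte-Carlo standard error of a ~99.7% fraction at ~0.17
percentage points.

## Synthetic studies

`synth` emulates the real dataset's shape: cyt b 327 bp with samples
22/43/27 (LAB/RAB/SCH) and three nuclear loci of 495/665/578 net sites
with the study's per-locus sample sizes. Nuclear demes scale the mtDNA
haploid sizes by 4 (diploid autosomal copy number); nuclear
`ts_proportion` is 0.5 (introns show no strong transition bias at these
divergences). In `mtdna_capture` mode the mitochondrial history reroutes
RAB ancestry through *R. schneideri*: RAB and SCH mtDNA share an ancestral
deme at the capture time (default 100,000 generations — a modeling choice;
no empirical estimate of the capture time exists), with the donor's size,
while LAB joins at the deep split.

The discordance signature is operationalised as: marina (LAB+RAB)
**non-monophyletic** on the cyt b NJ tree, while a **majority (≥2 of 3)**
of nuclear loci recover marina monophyly (through a positive-length edge).
Majority rather than unanimity acknowledges residual nuclear lineage
sorting — single intron loci at ~0.7% species divergence carry only a
handful of informative differences, and the real data also showed
incomplete sorting at nuclear loci within species groups.

What passing tests on these data do **not** show: the generator has no
geographic substructure within RAB, no haplotype-frequency realism (e.g. a
single widespread donor haplotype), no recombination in nuclear loci, no
sequencing error or phasing uncertainty. Results on real data with those
features can differ, particularly the PHI and Rm tests, which are
sensitive to phasing artefacts.

## Problem sizes and tolerances

Stochastic checks use sizes at which Monte-Carlo error is well inside the
asserted tolerance: 5000 replicates for the n=2 TMRCA expectation and the
total-length harmonic identity (±5%), 2000 for mean π̂ vs 2Nμ (±5%), 1000
observed draws against a 20,000-draw null for the type-I error of D
(binomial 95% band), 100 generated studies for the discordance signature
(≥90%), and 1000 bootstrap replicates for the monophyly fraction (±1.5
percentage points around the expected ~99.7%). Equality tests on closed
formulas assert to 1e-10/1e-12 relative; published table cells are
asserted at the precision to which their inputs were printed (3 decimals).

## Known limitations

* Fu's Fs beyond n ≈ 150 is untested (log-Stirling row cost is O(n²)).
* The PHI implementation is the biallelic binary-score variant; datasets
  rich in multi-allelic informative sites lose those sites.
* The coalescent simulator supports isolation histories only — no
  migration or growth — because the bootstrap's null model needs nothing
  more; gene-flow parameter estimation is explicitly an input, not a
  capability.
* The ambiguity between haploid sizes as printed vs halved again (the
  source describes both readings) is resolved in favour of the printed
  values; the ILS rejection is robust to a factor of two in deme sizes,
  though the exact monophyly percentage is not.
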
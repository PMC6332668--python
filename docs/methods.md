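# Methods

## Meiosis model

Meiosis in a polysomic polyploid is modelled at the level of whole-arm
bivalents. For each base chromosome with `k` homologous copies:

1. **Pairing.** Listed preferential pairs are resolved sequentially: each
   pair `{i, j}` with affinity `p ∈ [0, 1]` forms a bivalent with
   probability `p` (given both members are still free). The remaining
   homologs are matched uniformly at random over perfect matchings — each
   of the 15 matchings of 6 homologs has probability 1/15 when no
   preference applies. With odd `k` (compensated aneuploidy) one homolog
   remains univalent.
2. **Transmission.** Each bivalent contributes exactly one recombinant
   strand to the gamete: the strand starts from either member with
   probability 1/2 and switches member between adjacent loci with the
   Haldane probability `r = (1 − e^(−2d/100))/2` for a gap of `d` cM (no
   chiasma interference). A univalent enters the gamete with probability
   1/2 (unbiased default, configurable).
3. **Cross.** Hybrids combine a maternal and a paternal gamete; accidental
   selfs combine two independent maternal gametes and therefore carry no
   paternal-unique alleles. Reproductive mode is a fully penetrant
   dominant trait of the paternal ASGR haplotype; an independent Bernoulli
   fraction (default 25/102) is relabelled *undetermined* to emulate
   non-flowering plants and pistil losses.

Assumptions and exclusions: bivalents only (no multivalents, hence no
double reduction), no gametophyte selection, no segregation distortion
other than that produced by pairing itself. These suffice to reproduce
every single- and two-locus expectation the analysis relies on — simplex
1:1; duplex 4:1 (hexasomic), 5:1 (tetrasomic) and 5:1 for a duplex
confined to an always-co-pairing 4-homolog subgenome; and the
simplex–duplex class frequencies of the coupling model, which the test
suite verifies against the simulator at several `r`. Multivalent pairing
and double reduction would perturb the duplex ratios by a few percent at
realistic rates; modelling them is future work.

## Read-count model and genotype calling

Sequencing depth per marker and individual is Poisson (optionally negative
binomial) with mean `λ` (default 60) times a per-marker multiplier;
alternate-allele reads are Binomial(depth, dosage/c) with `c` the
individual's chromosome copy number.

One deliberate refinement: real GBS tags in a hexaploid with diverged
subgenomes are frequently conserved on only a subset of the homologous
copies, so the read pool at a heterozygous site samples ~4 rather than 6
chromosomes — empirically visible as a heterozygous read-frequency peak
near 0.25. The pipeline generator therefore sets `tag_copies = 4` by
default (allele fraction = dosage / min(4, c)). This matters: at an
allele fraction of 1/6 and `λ = 60`, the calling rule below would miscall
~13% of true heterozygotes as homozygous (the minor-allele-frequency
boundary), which is incompatible with LOD-7 two-point grouping at n = 102;
at 1/4 the miscall rate is below 1%. `simulate_reads` without the option
keeps the plain dosage/c binomial. The parent's own library uses 4× the
progeny depth (parents are routinely sequenced deeper; at 1× a simplex
parent call fails the MAF rule ~10% of the time and the marker loses its
informative parent).

Calling (presence/absence only, no dosage): heterozygote iff both alleles
have ≥ 2 reads and minor-allele read fraction > 0.10; otherwise homozygote
for the majority allele iff it has ≥ 11 reads (strict hexaploid mode: 17);
otherwise missing. A stray opposite-allele read that fails the
heterozygote rule does not block a homozygote call (the complement of the
heterozygote definition). Markers with > 20% missing calls are excluded
(strictly greater). The dead maternal parent is imputed from 12 selfed
progeny: homozygous iff all non-missing selfs are homozygous in the same
state; heterozygous iff the selfs are all heterozygous or segregating.
Progeny with an extreme excess of heterozygote calls (sample mixing) are
screened by a two-sided exact binomial test of the heterozygote count
against 0.5 over non-missing simplex calls, excluded iff P < 1e-10 *and*
the excess is in the heterozygote direction; fewer than 30 informative
markers → untestable, retained. The binomial construction is this
package's concrete substitute for an unspecified legacy statistic.

## Dosage classification

SDA iff the het:hom ratio lies strictly inside the symmetric 2:1 band
(both het < 2·hom and hom < 2·het; homozygote excess violates 1:1 just as
much as heterozygote excess). Otherwise the 5:1 and 4:1 duplex ratios are
tested by Pearson χ² (df 1, no continuity correction — immaterial at
n ≈ 102); an accepted ratio (P > 0.05) classifies the marker, the larger
P winning when both fit (flagged ambiguous). Markers heterozygous in both
or neither parent are outside the pseudo-testcross model and stay
unclassified. Only hybrids enter segregation counts; selfs exist solely
to impute the mother.

## Karyotyping

All marker-pair tests use the two-sided Fisher exact test on the 2×2 joint
presence/absence table over pairwise-complete individuals (pairs with
fewer than 10 complete cases are skipped). Direction comes from the
sample odds ratio with a Haldane–Anscombe 0.5 offset for zero cells
(direction only). P-values are cached under the table's row/column
symmetries, which keeps the ~10^5-table replicated studies affordable.

Significance tiers follow the conventional heatmap: 0.05, 0.001, 1e-5.
A linkage-group pair is called *coupled*/*repulsed* when more than half of
its marker pairs are significant at the outer tier in that direction;
group pairs with fewer than 4 marker pairs stay neutral (one significant
marker pair is not evidence about two whole groups).

Coupling-phase linkage groups: `r̂ = (n10 + n01)/n` clipped to
[1e-6, 0.5], `LOD = (n11 + n00)·log10 2(1 − r̂) + (n10 + n01)·log10 2r̂`,
single linkage over coupling-direction edges with LOD ≥ 7. Repulsion-phase
linkage is never used for grouping (its expectation depends on the
inheritance model).

Homolog clustering: connected components over (a) group pairs repulsed at
the **middle** tier and (b) group pairs sharing ≥ 2 unambiguously assigned
duplex markers. The middle tier is used for edges because an outer-tier
majority is reachable by a single chance correlation between two
internally linked marker blocks (a fragment of a split group can bridge
two chromosomes), whereas genuine anti-transmission reaches p < 0.001.
Component size = homolog count; a deviation from the expected copy number
is the aneuploidy signal.

Preferential pairing: a pair within a component is *preferential* iff it
is repulsed at the middle tier while neither member shows middle-tier
repulsion against any other component member; pairs involving groups with
fewer than 2 markers are untestable. Under random hexasomic pairing the
between-homolog repulsion is real but weak (co-presence 1/5 vs 1/4 at a
shared locus, and closer to 1/4 at distance), so it essentially never
reaches the middle-tier majority — that separation *is* the
discrimination property the acceptance study measures.

## Simplex–duplex coupling model

Closed forms as in the README table; the enumeration oracle reproduces
them to 1e-12 over a 51-point `r` grid for both models (a core test).
Independence is tested by Pearson χ² (df 3, no correction) against the
`r = 0.5` expectations, coupling declared only with P < 0.05 *and* an AB
excess (the model covers coupling phase only). `r` is estimated by
bounded 1-D maximisation of the multinomial log-likelihood on
[1e-6, 0.5]; endpoints are compared explicitly and boundary/degenerate
estimates flagged; a 1e-4 grid search serves as the oracle.

Duplex-to-homolog-pair assignment scores each group by the **largest**
signed independence-χ² over the group's SDA markers — a duplex couples
with the markers near it, so the best marker carries the evidence while
the median over a 100 cM group sits at the significance threshold and has
little power. The critical value is the α = 0.05 χ²(3) quantile
Bonferroni-corrected by the number of groups (the decision unit; markers
within a group are strongly correlated, so the within-group maximum is
only mildly anti-conservative). Exactly two passing groups assign the
marker; any other count flags it ambiguous/unassigned.

Subgenome uniformity: Pearson χ² of the duplex tally per homolog pair
against the uniform expectation total/k (k = 15, 10, 21 pairs for 6, 5, 7
homologs), df k − 1, with a small-sample flag when the total is below k.
In a strict allopolyploid no duplex is shared across subgenomes, so the
e/f pair and the a–d block form separate components; chromosome-level
uniformity in the replicated studies therefore uses the simulator's truth
for chromosome membership — the stand-in for the synteny information real
studies use to merge such groups.

## ASGR mapping

Pistil records fold all aposporous evidence (Panicum-type embryo sacs,
enlarged vacuolated nucellar cells) into one category: ≥ 10 normally
developed pistils are required for a call, any aposporous pistil makes the
plant apomictic, otherwise sexual. Monogenic segregation is tested by χ²
against 1:1 (df 1, no correction). The cosegregation scan counts
mismatches between allele presence and the apomictic state over phenotyped
individuals with non-missing calls; the perfect-linkage set requires zero
recombinants and ≥ 50 informative individuals.

The replicated recovery study runs the scan on the simulated genotype
matrix. Perfect cosegregation is intentionally brittle under genotyping
noise — a single miscalled heterozygote removes a marker from the
zero-recombinant set, and at `λ = 60` the per-call miscall rate of a few
per mille already breaks the full 5-marker block in a substantial fraction
of replicates (`use_read_calls=True` exposes this). Real studies absorb
such singletons by re-checking suspicious calls; modelling that curation
is out of scope, so the default study isolates the meiotic and scan logic.

## Study designs and problem sizes

All replicated studies use the mapping design: 102 analysable hybrids
(114 simulated minus 12 selfs), 12 evenly spaced simplex markers per
homolog over 100 cM, 60 duplex markers per chromosome (real parents carry
~50–75 heterozygous duplexes per chromosome). Pairing discrimination runs
one 6-homolog chromosome per replicate (its claims are per chromosome);
aneuploidy detection runs the full 2n = 36 complement with copy numbers
(6,6,6,6,5,7); ASGR recovery uses two chromosomes with a 5-marker
zero-recombination block. Even marker spacing reflects the intent of a
saturated map; with random spacing, occasional > 25 cM gaps split homolog
groups at LOD 7 and n = 102, a map-density effect rather than a property
of the statistics.

What passing these studies does **not** show about real data: robustness
to multivalent pairing and double reduction, to locus-specific read biases
and mapping artefacts beyond the tag-copies approximation, to phenotype
misclassification of reproductive mode, or to the manual curation steps
(synteny-based group merging, marker re-scoring) that real mapping
projects interleave with the statistics.

## Numerical choices

- Haldane map function throughout; `r̂` clipped to [1e-6, 0.5] before
  logs; LOD of a perfectly cosegregating pair ≈ n·log10 2.
- Fisher p-values cached by canonical table symmetry; equality with
  direct scipy calls is asserted in tests.
- Ties between 5:1 and 4:1 dosage fits resolved by larger P, flagged.
- ML boundary estimates compared against both interval endpoints
  (`minimize_scalar` never returns an exact bound).
- All randomness flows from one seed through `numpy.random.SeedSequence`
  spawning; identical seeds reproduce populations bit for bit.
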
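# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, and what the synthetic data does and does not emulate.

## Haplotype model and filters

The locus is modelled as a clonal haplotype block: each accession descends
from one of a small number of founder haplotypes, with no recombination
inside the block. This matches the biology of a sub-megabase candidate
interval in a selfing crop, where effective recombination within the locus
is negligible over breeding timescales; it would be wrong for outcrossing
species or intervals spanning recombination hotspots.

Filtering follows the two-stage rule used for exome-capture diversity
panels, with both thresholds strict:

- **Sites**: minor-allele frequency must exceed `maf_min` (default 0.05).
  "Allele frequency" is read as *minor*-allele frequency over non-missing
  allele counts (a homozygote contributes two copies, a heterozygote one of
  each). The alternate-allele reading was rejected because it makes the rule
  asymmetric under REF/ALT swaps, which are arbitrary artifacts of the
  reference assembly.
- **Accessions**: the fraction of homozygous calls among *non-missing* calls
  over the *kept* sites must exceed `hom_min` (default 0.80). Missing calls
  are excluded from the denominator: a sparsely genotyped but fully inbred
  line should not fail a homozygosity screen. An accession with no
  non-missing calls is treated as 0% homozygous and dropped.

A consequence worth noting: because the homozygosity denominator is the kept
site set, raising `maf_min` changes that denominator, and accession counts
are monotone in each threshold only in the regimes the property tests cover;
site counts are always monotone.

Haplotype reconstruction is deliberately conservative: an accession with any
heterozygous or missing call over the defining sites is reported as
unassigned with the offending sites, never imputed. The >80% homozygosity
filter already implies near-complete homozygosity was expected of usable
lines. Haplotypes are named H1, H2, … by descending member count, ties
broken by first occurrence in accession order, so output is deterministic.

The informative-SNP subset is a greedy set cover: candidates are sites with
accession-weighted MAF > 0.30; each step adds the site resolving the most
still-unresolved haplotype pairs (ties: larger MAF, then left-most
position). Greedy set cover is within a logarithmic factor of optimal and,
on panels of this size, routinely finds subsets that resolve all pairs; an
exhaustive search (`exhaustive=True`) is available for small candidate sets
and doubles as the oracle in the tests. No published algorithm exists for
this selection step, so the criteria (distinguishing power, common alleles)
were taken as the definition and the algorithm is this package's choice.

New panels are typed by exact matching of homozygous subset strings against
reference-haplotype projections. Projection collisions are reported as
compound labels (`H5/H7`) rather than resolved arbitrarily — the subset
genuinely cannot tell the references apart. Novel strings get panel-local
names N1, N2, … so downstream tables never confuse them with reference
haplotypes.

## Median-joining network

Distances are Hamming counts over the allele strings with all sites weighted
equally (weights are exposed as a future extension point, not used). The
ε-relaxed minimum spanning network includes edge (u, v) iff
d(u, v) ≤ bottleneck(u, v) + ε, where the bottleneck (minimax path weight)
is computed from a minimum spanning tree; at ε = 0 this is exactly the union
of all MSTs. ε defaults to 0, the default of the desktop program
conventionally used for such figures.

Median insertion exploits the biallelic alphabet: the quasi-median of three
strings is their position-wise majority (three distinct states at a position
are impossible). Candidates are majorities of connected triples (two MSN
edges sharing a node); the candidate giving the largest reduction in total
connection cost (MST cost over the node set) is added, ties broken by
lexicographically smallest string, until no candidate improves. Each
accepted median reduces an integer cost bounded below by zero, so the loop
terminates. Inferred nodes with MSN degree ≤ 2 are pruned afterwards — by
the triangle inequality a degree-2 median cannot reduce cost — and observed
haplotypes are never pruned.

On every instance with ≤ 5 observed haplotypes over ≤ 4 sites the
construction reaches the brute-force Steiner optimum (verified exhaustively
in the test suite); for larger instances it is a greedy heuristic, as is
every practical median-joining implementation. Median placement may
legitimately differ from other programs whose ε and star-contraction
preprocessing are unreported.

## Population statistics

Percentages are rounded to the nearest integer with ties away from zero,
the convention consistent with published germplasm survey tables. The 2×2
association test is the Pearson χ² without continuity correction with df = 1
(delegated to `scipy.stats.chi2_contingency(correction=False)`); the
no-correction choice is validated by exact reproduction of the published
statistic 8.497 on the 41-variety market-class table, which a
Yates-corrected statistic would miss materially. A warning is emitted when
any expected count falls below 5 (the smallest expectation in the published
table is ≈ 6.3, above the cutoff).

## Coefficient of parentage

The inbred-line convention is used: COP(x, x) = 1, distinct founders 0,
unknown parents contribute 0 relatedness, and
COP(x, y) = ½·[COP(x, p₁(y)) + COP(x, p₂(y))] expanding the deeper
(descendant-side) line. For fully homozygous lines this is the probability
that alleles drawn from the two lines are identical by descent, and it is
the standard convention in wheat germplasm diversity work; no kinship/2
factor is applied. The recursion is memoized; depths guarantee the expanded
line is never an ancestor of the other, so it terminates on any DAG (cycles
are rejected at construction).

Group means exclude lines absent from the pedigree table (lines with wholly
unknown pedigrees carry no information and would bias means toward zero);
founders recorded with unknown parents are legitimate lines and are kept.
Pair counts are n(n−1)/2 within groups and |a|·|b| between disjoint groups.

The published group means themselves (0.10–0.21) depend on a proprietary
pedigree database and are not reproduced here; the implementation is instead
validated three ways: hand-derivable cases (parent–offspring 0.5, full sibs
0.5, half sibs 0.25, founders 0) exactly, an independent unmemoized
recursion exactly, and a vectorized gene-dropping Monte-Carlo oracle (each
line carries one allele; a child copies a uniformly chosen parent's allele;
unknown parents contribute fresh unique alleles) within 3 standard errors at
10⁵ drops per spot check. Because a hard 3-SE bound over 50 spot checks is
expected to produce an occasional excursion even for an exact recursion, a
check that exceeds it is re-estimated with two further independent
replicates and the pooled estimate must agree — a real bias persists under
pooling, a fluctuation does not.

## Marker design

Restriction sites are matched as IUPAC motifs on both strands (reverse-
strand sites found by matching the reverse-complement motif on the forward
strand, reported in forward coordinates; palindromic motifs deduplicated).
A forward site starting at p with cut offset c cuts after base p + c − 1; a
reverse site cuts after p + (L − c) − 1, the mirror of the offset. Hpy166II
is modelled as a blunt cutter, GTN^NAC (offset 3); the enzyme table is a
plain TSV so other conventions can be swapped in. Fragment ladders always
sum to the amplicon length, and a CAPS assay is "discriminating" iff the two
alleles' sorted ladders differ; assays are ranked by the largest band-size
difference a gel must resolve.

KASP records are positional, not thermodynamic: the allele-specific primers
are the fixed-length window ending at the SNP on the chosen strand (reverse
orientation takes the reverse complement, so the 3′ base is the complement
of the allele), the common primer comes from the opposite strand at the far
template end, and the FAM tail is prepended to the first-listed allele's
primer, HEX to the second. The shipped tail sequences are the de-facto
standard dye tails; melting temperature, hairpin and genome-specificity
screens are out of scope (the published primers were position-designed
against homoeologue alignments unavailable here).

## Synthetic data: what it emulates and what it does not

The generator plants `n_founder_haplotypes` pairwise-distinct, fully
segregating allele strings; assigns each accession one founder (every
founder used at least once, remaining draws categorical, optionally with a
fixed frequency vector so a major-haplotype share can be planted); and
corrupts calls independently — missing with probability `missing_rate`,
else heterozygous with probability `het_rate` (mutually exclusive, missing
first, so the probability accounting is unambiguous). Founder assignments
are redrawn until every site's planted minor-allele frequency reaches
`maf_floor` (default 0.10, comfortably above the 5% filter so planted sites
survive filtering and distinct founders cannot collapse). By default the
first accession carrying each founder is left uncorrupted, emulating panels
in which every haplotype is anchored by at least one fully homozygous line —
the regime in which exact haplotype-count recovery is a meaningful check.

Default noise rates (het 5%, missing 5% for general use; the panel-recovery
study uses 2%/2%) are configuration choices for a clean inbred diversity
panel, not estimates of any particular dataset — the true heterozygosity of
the original exome-capture calls is unpublished. The generator is clonal:
no coalescent genealogy, no recombination, no allele-frequency spectrum
realism, no genotyping-error model beyond the two corruption modes, and no
linkage structure beyond perfect linkage. Passing tests therefore
demonstrate correctness of the *inference machinery* under the stated block
model, not robustness to recombinant or outbred real-world panels.

Amplicon pairs are built by planting one motif realization at a fixed
position, breaking it with a single substitution at a non-degenerate motif
base, and mutating away any spurious motif occurrences (with rejection and
retry if the planted window itself is compromised), so the assay truth —
which allele cuts, and into what fragments — is known by construction.

## Problem sizes and determinism

The shipped study sizes mirror the panel the pipeline targets: 58 accessions,
39 sites, 14 founders. The exhaustive median-joining/Steiner cross-check
runs over all 7,117 instances with ≤ 5 observed haplotypes over ≤ 4 sites;
gene-dropping uses 10⁵ drops per spot check over 50 random pedigrees of
≤ 30 lines. Every generator and every pipeline stage is deterministic given
a seed (numpy `default_rng` throughout); the command-line tools record the
package version, command line and seed in a comment header of each output
table.
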
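# Methods

## Scope and model

`replitype` genotypes a multigene amplicon family from replicated,
dual-barcoded amplicon sequencing, estimates per-allele relative
amplification efficiencies, and computes alignment-level diversity, selection
and supertype statistics. The classification logic assumes two things about
artefacts: they are less frequent than their source allele within an
amplicon, and replicate amplicons (independent PCRs of the same DNA, in
different pools, under different barcodes) share true alleles but not most
artefacts. Everything else follows from those two assumptions.

## Read model and the synthetic-data generator

The simulator emulates the replicated 454-style design end to end so that
every stage of the pipeline can be measured against known truth. Defaults are
the study-design constants and are not tuned per experiment:

| parameter | default | meaning |
|---|---|---|
| samples × replicates | 320 × 2 | 8 pools of 80 amplicons |
| MIDs | 9 forward × 9 reverse, 10 bp | 81 combinations per pool; tags differ by ≥ 3 bases |
| template | 240 bp, codon-clean | between a degenerate forward primer (2 × Y) and the reverse primer |
| pool | 22 alleles, 2 with one in-frame 3-nt insertion | derived from a shared ancestor, ~5.5 % of sites substituted per allele (pairwise k ≈ 25–27) |
| loci | 6, alleles assigned round-robin | Hardy–Weinberg draws per locus; homozygous locus ⇒ copy number 2; 4–12 distinct alleles per bird |
| efficiencies | U(0.5, 2.0), reference fixed at 1 | per-allele, genotype-independent |
| reads/amplicon | negative binomial, mean 1430, shape 5 | matches the heavy-tailed depth spread of a real run (observed range ~45–4,000) |
| substitutions | 5 × 10⁻⁴ per base | per-read Binomial |
| indels | 0.05 per read, 1–2 bp | one event max per read |
| chimeras | 2 % of reads | parents ∝ parent read counts, breakpoint uniform |
| early-PCR lineages | Poisson(10) per amplicon | each a 1–2 bp variant of one allele at a fraction 2^−U(1,5) of its parent's weight |
| singleton junk | 0.5 % of reads | 3-substitution mutants, effectively unique |
| qualities | two-state, Q37 / Q12, 2 % low | makes the "Phred > 20 at > 95 % of bases" filter crisp |

The early-PCR lineage class deserves a comment because it is what makes the
replicate comparison meaningful. An error in an early PCR cycle is inherited
by an exponentially growing share of the product, so real amplicon data
contain *recurrent, high-frequency, replicate-specific* artefact clusters —
frequently above the intra-amplicon frequency of the weakest true alleles.
Without this class every artefact would be a near-singleton, step 3's
frequency comparison would be vacuous, and low-efficiency alleles would never
be pushed onto the unclassified list the way they are in real data. The
lineage fraction range (½ down to 1/32 of the parent) corresponds to an error
arising in roughly cycles 1–5.

Because allele sequences are drawn as an allele family (common ancestor plus
independent substitutions), chimeric reads collapse into recurrent clusters,
as they do when real alleles share most of their sequence.

What the generator does **not** model: flowgram-level homopolymer noise,
emulsion-PCR duplicate structure, contamination between samples, primer-bias
interactions with template secondary structure, and alleles related by gene
conversion (simulated alleles get independent substitution sets). Passing the
simulation-based tests therefore demonstrates the pipeline's logic under the
stated error classes, not its performance on every real-data pathology.

Randomness: one master seed feeds named substreams (pool, genotypes,
efficiencies, depths, per-amplicon reads), so components are independently
reproducible and FASTQ output is byte-identical for a fixed seed.

## Classification details and tie-breaks

* Clusters sort by count descending, ties broken lexicographically. All
  clusters tied at the maximum count become putative alleles (symmetric; no
  arbitrary loss).
* The chimera test asks whether a cluster equals a length-k prefix of one
  strictly-more-frequent cluster joined to the matching suffix of a
  *different* strictly-more-frequent cluster, for any internal k. The
  pipeline uses an O(n·L) longest-common-prefix/suffix formulation proved
  equivalent to the explicit scan (a breakpoint k exists iff
  lcp(q, A) + lcs(q, B) ≥ |q| with both ≥ 1 for some A ≠ B); tests enforce
  the equivalence exhaustively. The chimera label takes precedence over the
  distance labels.
* "1–2 bp difference" uses Levenshtein distance (substitutions and indels),
  computed against strictly-more-frequent clusters only, with an early exit
  at distance ≤ 2.
* Step 3 compares a cluster's intra-amplicon frequency with the maximum
  artefact frequency *of the same amplicon* (an empty artefact list passes
  vacuously), and requires the comparison to succeed in both replicates
  before promoting. Amplicon-local scope was chosen because frequencies are
  amplicon-normalised; the per-replicate conjunction keeps the rule symmetric
  with the "present in both replicates" requirement.
* One-replicate clusters are resolved against the provisional putative-allele
  sets of other samples in a single pass (no fix-point iteration): a >2 bp
  cluster seen as an allele elsewhere stays unclassified, otherwise it
  becomes an artefact; a retained chimera becomes an allele if its sequence
  is an allele elsewhere, otherwise it stays unclassified.
* Large-cohort post-processing order: (a) drop putative alleles seen in < 2
  individuals, then promote (b) catalog-matching unclassified variants and
  (d) catalog-matching artefacts present in both of a sample's amplicons
  above the amplicon's least frequent called catalog entry, then (c) flag
  unclassified variants present in both amplicons of > 80 % of individuals
  as low-efficiency alleles. Promotions never resurrect dropped alleles; the
  low-efficiency flag can, because it operates on the unclassified list
  itself (that is precisely how chronically under-amplifying alleles
  resurface). Flagged alleles are retained in the catalog for sequence-level
  analyses but carried as flags in the per-sample calls, since their
  presence/absence cannot be trusted sample by sample.
* Small-cohort rules: an allele confirmed in both replicates of even one
  sample is kept; an allele called once but seen elsewhere as an unclassified
  variant is kept; unclassified variants present in both replicates of ≥ 2
  birds are promoted.
* Matching is exact string equality on trimmed templates throughout.
* Repeatability uses the union denominator (Jaccard × 100); both calls empty
  is undefined and raised as an error.

## Quality filtering and demultiplexing

The read filter is strict on both comparisons: a read passes iff the count of
bases with Phred strictly greater than 20 exceeds 95 % of its length. MIDs
must match exactly (the tag set guarantees ≥ 3 differences between tags);
primers match IUPAC-aware at the expected offset, with no fuzzy alignment.
Reads are single-orientation; an optional fixed key prefix (e.g. TCAG) is
accepted. `n_raw = n_assigned + n_filtered + n_unassigned` holds for every
pool.

## Efficiency estimation and T1

Within-amplicon pairs with both counts ≥ 1 contribute `log(n_i/n_j)` with the
amplicon's total reads as weight; the normal equations are solved with the
reference column removed, and alleles not connected to the reference through
shared amplicons are reported as missing rather than guessed. No pseudo-counts
are added. The estimator assumes one template copy per called allele; where
a genotype is homozygous at an unphased locus the true weight doubles and the
estimate absorbs the bias (visible as ê up to ~20 % above truth for common
alleles in the simulator, where homozygosity is explicit). This is a known
limitation of efficiency estimation over unphased multigene families, not of
the solver.

T1 is defined here as the conservative worst case: the smallest `N` with
`P(Binomial(N, p_min) ≥ m) ≥ coverage`, `p_min = e_min/(e_min + k − 1)` —
i.e. the rarest allele competes against `k − 1` average amplifiers. It is
applied to each replicate independently, and a sample is excluded iff either
replicate falls strictly below `N`. The original function this mirrors lives
in third-party supplementary scripts; this implementation is validated by its
monotonicity properties (N non-increasing in `e_min`, non-decreasing in `k`,
`m` and coverage), not by reproducing any specific printed threshold.

## Sequence statistics

Alignment-wide statistics use complete deletion (columns containing any gap
are excluded): `S` = columns with ≥ 2 states, `η` = Σ (states − 1),
`k` = mean pairwise differences, `π = k/L`, `θ = η/a_{n−1}` (a flag switches
to the `S`-based form; published tables rarely say which convention generated
them, so θ comparisons should be treated as indicative). `R_m` follows
Hudson–Kaplan: all biallelic site pairs showing four gametes define open
intervals, and the maximum number of pairwise disjoint intervals is the lower
bound on recombination events.

NG86 counts synonymous sites per codon as the per-position fraction of
synonymous single-base changes, with changes to stop codons counted as
non-synonymous; multi-step codon differences average over all minimal
substitution pathways, excluding pathways through stop codons (a codon pair
whose pathways are all blocked contributes sites but no differences). Codon
pairs containing a gap are skipped pairwise. `p = d/sites` is Jukes–Cantor
corrected, `d = −¾ ln(1 − 4p/3)`, undefined (reported missing) at `p ≥ ¾`.
Partition summaries (full / PBR / non-PBR, the PBR supplied as a 1-based
codon index file since it comes from prior structural work) report mean
pairwise `d_N`, `d_S`, their ratio, and a two-sided Mann–Whitney U comparing
the off-diagonal `d_N` and `d_S` values. The rank test treats pairwise
distances as independent observations, which they are not; this follows the
field's convention and should be read as descriptive, not inferential.

## Supertypes

Unique protein sequences over the analysed positions are encoded with the
five published z-scale descriptors per residue (shipped as a versioned data
file; Sandberg et al. 1998, J Med Chem 41:2481). Positions where any sequence
carries a gap (the one-residue insertion) are dropped by default; a strict
mode errors instead. k-means (k-means++ initialisation, 100 iterations,
tolerance 10⁻⁶) runs `n_runs = 4` times per k from derived seeds;
`BIC = n·ln(WSS/n) + k·ln(n)` is averaged per k and the minimum chosen, ties
to the smaller k. WSS is floored at machine epsilon so the BIC stays finite
at perfect fits; with fully distinct, well-separated rows the minimum
therefore falls at `k = n` — the all-singleton outcome in which every allele
is its own supertype. No PCA pre-step is applied by default, because the
clustering procedure is defined directly on the descriptor matrix here; note
that BIC selection on raw descriptors has weak resolution at low
dimensionality (the k → k+1 WSS drop of splitting a spherical cluster scales
like 1/d), so it is most reliable in the realistic regime of 5 × (10–15
positions) columns.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open internally, 1-based in serialised reports.
Empty amplicons are an error for clustering and frequency computation; a
missing replicate skips the cross-validation step for that sample and the
sample is reported excluded. A disconnected allele in the efficiency graph is
missing, not zero. `jukes_cantor` uses `log1p` for small-p accuracy. The
chimera fast path pads sequence matrices with row-distinct sentinels so
prefix/suffix matches never extend past either sequence's end.

## Problem sizes used in validation

The validation suite measures genotype recovery and repeatability on
310 samples × 2 replicates × 5 seeds at mean depth 1430 (≈ 4.5 M reads
simulated and classified in ~30 s), dropout flagging on two 60-sample cohorts
of forced 12-allele genotypes, chimera-detector equivalence on 10⁴ randomised
cluster sets, efficiency recovery on 5 × 200 amplicons of 1000 reads, and
oracle equivalence for `R_m` (100 alignments of 20 × 30 with known
crossovers) and NG86 (20 random 30-codon pairs, agreement to 10⁻¹⁰).
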
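# Methods

## Data model

Strains are treated as haploid. Wild-isolate panels of a selfing species
are nearly fully inbred, so diploid VCF calls collapse on ingest
(0/0 → 0, 1/1 → 1) and residual heterozygous calls become missing data
rather than half-alleles. Only biallelic single-nucleotide records are
kept; sites with a missing fraction above `max_missing_fraction`
(default 0.05) are dropped. The default is deliberately strict — with a
panel of ~20–150 strains a 5% missing ceiling keeps per-site allele
counts close to the panel size — and is exposed as configuration because
published scans vary in how they handle missingness.

Gene family classes are a pure function of the gene name: the token
before the first hyphen is matched case-insensitively against three
configurable prefix lists (chemoreceptor serpentine-receptor families
sra…srz/str; fast-evolving controls fbxa/fbxb/fbxc/clec/nhr; essential-
phenotype purifying proxies unc/bli/let/dpy/rol/egl). Exact-token
matching means `srxl-1` is *not* a chemoreceptor even though `srx-1` is.

## Windowed Tajima's D

Windows are 0-based half-open `[k·w, (k+1)·w)` anchored at coordinate 0
of each chromosome (default w = 5000 bp), matching the conventional
binning of vcftools-style scans; a 1-based site at position p falls in
bin `floor((p−1)/w)`. Per site, π uses called alleles only
(2j(m−j)/(m(m−1))), while the variance constants a₁, a₂, b₁, b₂, c₁,
c₂, e₁, e₂ always use the full panel size n — a robust default when
missingness is light; a strict mode drops any site with a missing call.
D is undefined (NaN, written as `nan`) when S = 0 or the variance term
vanishes; such windows are "unscored" and excluded from tail counting.
Without chromosome lengths only windows overlapping ≥1 site are
reported; with lengths, every window is.

The scan TSV uses the four-column CHROM / BIN_START / N_SNPS / TajimaD
dialect with D rounded to four decimals, so files interoperate with
tooling that consumes vcftools `--TajimaD` output.

## Tail enrichment

A window "contains" a class when any gene of that class overlaps it at
all (a gene spanning a boundary annotates every window it touches); an
alternative gene-start-in-bin rule was considered and rejected as the
less literal reading of "contained", but the annotation keeps full gene
lists per bin so either can be recomputed. Both tail and genome-wide
fractions are computed over scored windows only, keeping numerator and
denominator on the same support. Default tail thresholds are ±2.5 and
the candidate cutoff D > 1; all are configuration, not constants. Class
flags are independent (a bin may contain both an essential gene and a
chemoreceptor); the histogram's per-bar colouring uses the priority
chemoreceptor > fast-evolving > purifying-proxy.

## Shared-haplotype signature

"Present on a shared haplotype" is operationalised as exact identity of
induced bipartitions — perfect linkage disequilibrium — not a
four-gamete compatibility relation: each fully-called polymorphic SNP
splits the panel into carriers and non-carriers, canonicalised so the
side containing the first strain is listed first (ref/alt labels and
strain order cannot matter). SNPs with any missing call are excluded
from numerator and denominator alike so the shared fraction stays a
well-defined proportion. The modal bipartition breaks ties toward the
more balanced split, then lexicographically. A candidate must both
exceed the shared-fraction cutoff (default 0.5, strictly) and overlap a
scored window with D above the cutoff (default 1.0): the two filters are
applied as a conjunction. Gene span is the annotated gene interval; no
promoter flank is added.

## Counting dN/dS

Each variant is classified independently against the reference codon
under the standard genetic code (no compound-codon pathways), matching
per-variant annotator behaviour; nonsense changes count as
nonsynonymous. Potential sites follow the Nei–Gojobori counting
convention: per codon position, the fraction of the three possible
substitutions that are synonymous accrues to S sites and the rest to N
sites, with substitutions creating stop codons excluded from both — so
N + S + excluded = 3 × codons exactly. dS = 0 leaves the ratio NaN,
never 0. No multiple-hit correction is applied: the counts are
within-species and small, so raw proportions are reported and a
Jukes–Cantor correction would move them negligibly. When a gene has
several transcripts the longest CDS is used. Minus-strand transcripts
complement alleles and mirror coordinates; CDS offset 0 is the genomic
3′ end.

## Synthetic data

The generators emulate the statistical structure of a wild-isolate
panel, not its biology:

- **neutral** — a direct pair-merge coalescent (waiting time
  Exp(k(k−1)/2) while k lineages remain) with infinite-sites mutations
  at θ/2 per unit branch length, one independent genealogy per window,
  sites placed uniformly without replacement. Defaults n = 20, θ = 10
  per 5-kb window give E[S] ≈ 35, a polymorphism density in the range of
  diverse wild panels. The coalescent is implemented directly so the
  simulator is itself under test; msprime serves only as an independent
  test-time oracle.
- **sweep** — the same genealogy with external branches multiplied by a
  singleton-excess factor (default 10), approximating the star-like
  trees after a recent sweep. Factor 1 *is* the neutral model, by
  construction.
- **balanced** — k sites fixed between two fixed strain groups (default
  10 + 10, k = 50) over within-group neutral variation at θ_w; all
  diagnostic sites induce one bipartition, the haplotype structure the
  signature detects. A helper derives θ_w from a target inter-lineage
  SNP proportion p via E[S_within] = k(1−p)/p.
- **annotation** — class-labelled genes placed wholly inside scored
  windows, chemoreceptors with propensity e on extreme windows
  (|D| > 2 by default). Because bin occupancy is 1−(1−q)^G, the
  *bin-level* fold implied by a placement factor e is slightly below e;
  the truth table therefore records the exact expected occupancy
  fractions and expected fold, and recovery is judged against those
  with binomial confidence intervals.
- **coding genes** — a random stop-free CDS (ATG + sense codons) with
  requested numbers of synonymous and nonsynonymous changes planted at
  distinct offsets as inter-lineage SNVs, classes verified by
  enumeration at plant time.
- **study** — a mixed chromosome (defaults: 120 neutral, 15 sweep, 15
  balanced, 10 coding-gene windows, n = 20) in which balanced and
  coding windows share one genome-wide bipartition (two deep lineages),
  coding genes carry planted counts drawn from n ∈ [0,10], s ∈ [5,25]
  (bracketing the 5/20 scale typical of a conserved chemoreceptor
  allele pair) plus flanking inter-lineage sites that keep their
  windows' D high, and background genes of all classes are placed
  uniformly.

What the generators deliberately lack: recombination within windows,
gene conversion, demographic structure beyond the two-lineage split,
sequencing error, and variable mutation rate. Passing tests therefore
demonstrate correctness of the statistics and the recovery machinery on
data satisfying the models' assumptions — not robustness of the scan to
demography or data quality on real panels.

## Numerical choices and degenerate inputs

- Constants demand n ≥ 2; at n = 2 the variance term degenerates
  (c₁ = c₂ = 0) and D is undefined for any S.
- D's closed form is evaluated in double precision; tests pin it to the
  exactly-evaluated rational value of the n = 4 worked example
  (−0.7544510776…).
- Windows with S = 0 and genes with zero usable SNPs are flagged, never
  silently scored.
- Determinism: every generator and the whole pipeline are pure
  functions of config + seed; report bundles are byte-identical across
  reruns (manifests carry a config hash and no timestamps).

## Problem sizes

Defaults throughout target desk-scale verification: 500-window
simulation batches for sign behaviour, 100–200 seeded replicates for
recovery experiments, a 160-window synthetic study for the end-to-end
run. All scale linearly in windows × panel size; real-panel scans
(~20,000 windows × 152 strains) run through the same code paths via the
CLI.
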
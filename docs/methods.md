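# Methods

## Problem and model

`alienmark` implements the marker-discovery funnel used in wheat-alien
introgression breeding, with rye as the reference donor: find sequences
present in every cultivar of an outcrossing donor species but absent from
the host genome, place each on a single donor chromosome arm using a
diagnostic panel of addition lines, and convert placed markers into
co-dominant KASP assays whose endpoint fluorescence separates
alien-present, alien-absent and mixed samples.

The funnel has five stages:

1. **Locus extraction.** Complete in-silico digestion with a blunt
   four-cutter (RsaI, `GT^AC`), inclusive size selection of 464-494 bp
   fragments (the electrophoresis window of the reduced-representation
   protocol), and greedy centroid clustering at >90% identity into loci.
2. **Specificity.** A locus is donor-specific when its best local
   alignment against the host scores below 0.5, where the homology score
   is `identity x query coverage` of the best hit. The composite score is
   deliberate: a bare homology-below-50% criterion is ambiguous between
   identity and coverage readings, and the product is conservative under
   both. Both
   components are reported so users can re-filter. Specific loci present
   in every cultivar with all pairwise identities >= 0.90 become conserved
   donor-specific loci; the consensus is the first cultivar's member
   verbatim, since primers must sit on observed sequence.
3. **PCR markers and placement.** Primer pairs (18-25 nt, Tm target 60
   degC, GC 30-70%, product 100-450 bp) are designed on conserved loci and
   scored by `|Tm - target| + GC deviation`. In-silico PCR uses a mismatch
   policy of at most 2 mismatches per primer, none in the 3'-terminal
   3 nt, product <= 2 kb — the standard allele-discrimination assumption,
   standing in for wet-lab banding. The assignment rule engine then reads
   a boolean marker x line matrix over the panel: amplification in every
   cultivar but not the host (universal), in the alien control and exactly
   one disomic addition line (chromosome), and in exactly one
   corresponding ditelosomic line (arm). Any positive in a
   non-corresponding ditelosomic line rejects the marker; positives in
   both or neither corresponding ditelosomic lines leave it placed at
   chromosome level with an empty arm field. Placed markers are
   re-validated on a second, independent addition-line panel.
4. **KASP conversion.** The marker's source locus is anchored to a donor
   scaffold set (unique iff best hit identity >= 0.95 and no second hit
   >= 0.90) and the anchor is expanded by 5 kb to reach host-homologous
   flanking sequence — donor-specific cores themselves have no host
   homolog, so diagnostic SNPs necessarily come from the shared flanks.
   Against the host, every aligned mismatch column is accepted as a
   diagnostic SNP only if it is the single mismatch within 40 clean
   columns on each side (40-120 bp flanks, per side), indel-adjacent
   columns excluded, and the surrounding window matches the host at
   >= 0.90 identity. The assay comprises two allele primers sharing one
   footprint that ends exactly on the SNP (FAM-tailed for the alien
   allele, HEX-tailed for the host allele; tails
   `gaaggtgaccaagttcatgct` / `gaaggtcggagtcaacggatt`) plus a common
   reverse primer in the right flank with a 50-120 bp product. Allele
   primers extend 5'-ward until the Tm target is reached; assays whose
   in-silico genotypes on the panel deviate from expectation (host
   control homozygous host, alien control homozygous alien, arm carriers
   heterozygous) are discarded, mirroring the wet-lab validation step.
5. **Genotype calling.** Samples on the FAM/HEX plane are gated against
   the no-template cluster (mean + 3 sd of declared NTC magnitudes, or a
   configured floor), normalised to unit vectors, and clustered by
   spherical k-means seeded at the three genotype directions (0, pi/4,
   pi/2). Confidence is the gap between best and second-best cosine
   similarity, normalised by the 45-degree cluster spacing; samples
   below a 0.10 margin are `no_call`. In hemizygous alien-arm screens,
   carriers are counted as heterozygous plus alien-homozygous calls,
   because one alien arm in a host background yields both alleles.

## Melting temperature

All Tm values use the unified nearest-neighbor model (Allawi & SantaLucia
1997 parameters; 50 mM monovalent salt, 25 nM per strand, SantaLucia 1998
entropy salt correction). Under this parameter set typical 17-22 nt KASP
allele primers melt near 50-52 degC, so the allele-primer extension target
is 52 degC; the PCR-primer ranking target of 60 degC is a ranking
preference, not a threshold, and tolerates the same scale.

## Numerical and algorithmic choices

- **Alignment backends.** Pairwise identity (clustering, conservation) is
  an end-free alignment computed with edlib: the shorter sequence aligned
  globally, the longer sequence's ends free, identity = matched columns /
  alignment columns. Host-homology search, scaffold anchoring and SNP
  alignment run through `blastn` (dust off, deterministic), the
  batch-scale aligner a practitioner would use for host-reference
  comparison; tests cross-check its classifications against an explicit
  Smith-Waterman oracle on small inputs.
- **Greedy clustering vs single linkage.** The greedy centroid pass
  (descending length, first representative above threshold wins) is
  deterministic and linear in practice; on chained similarities it can
  split what single linkage would merge. The suite pins this divergence
  as a documented limit and verifies exact agreement on well-separated
  families.
- **In-silico PCR scanning.** Binding sites are found with a vectorised
  scan that first requires the 3'-terminal trigram to match exactly —
  that is the clamp policy itself, so the prefilter is exact — then
  counts remaining mismatches. Both primer-role orientations are
  considered; scans are memoised per (primer, contig) so panel lines
  sharing contigs are scanned once.
- **Caller symmetries.** All caller decisions are built from commuted
  sums and products of the two channels, so swapping FAM and HEX swaps
  the homozygote calls bit-exactly, and multiplying both channels by a
  common factor leaves the discrete calls unchanged.
- **Coordinates** are 0-based half-open everywhere; the size-selection
  window is inclusive at both ends; palindromic sites are scanned on the
  forward strand only.

## Synthetic study conditions

The simulator emulates the five-cultivar reduced-representation design
with one held-out donor (the addition-line parent). Defaults, chosen once
as the package's reference conditions:

| parameter | default | rationale |
| --- | --- | --- |
| host | 2 chromosomes x 750 kb | large enough for realistic homology search, small enough for desk-scale runs |
| alien | 7 chromosomes x 750 kb | seven donor chromosomes, as in the rye system |
| background identity to host | 0.99 | makes non-specific loci clearly host-like and provides ~1 diagnostic mismatch per 100 bp of flank |
| specific regions | 56 per Mb, 4-8 kb each, arm-balanced | about 21 regions per arm at ~30% of each chromosome; with the natural RsaI / size-window yield (~0.35 discoverable loci per region) every arm receives several markers with high probability |
| cultivar divergence | 0.005 outside conserved regions | outcrossing-donor heterogeneity; conserved regions are kept identical so universal markers exist by construction (a flag lifts this to probe universality failure) |
| centromere | chromosome midpoint; no region straddles it | the arm convention is recorded in the truth table so tests never depend on it implicitly |
| fluorescence | class means 1.0 / 0.08, NTC 0.06, sd 0.05 | well-separated endpoint clusters, as on a clean plate |

Mutations are substitution-only, keeping host, cultivar and line
coordinates directly comparable and the truth table exact. The test suite
runs the funnel on a reduced instance (3 chromosomes x 120 kb) and the
acceptance script on the full defaults.

What the simulator does **not** model: read-level errors and quality
scores, partial digestion, PCR efficiency and amplification bias, repeat
families and paralogy in the host, indel divergence, and
passive-reference (ROX) drift in fluorescence. Passing tests therefore
demonstrate the correctness of the decision logic and assay construction
under clean, coordinate-exact conditions — not robustness to repetitive
genomes or noisy libraries.

## Known limitations

- Homology scores come from blastn's best HSP; on borderline loci
  (~0.5 score) the composite can differ slightly from an exhaustive
  Smith-Waterman optimum, and fragments straddling a region boundary may
  be kept as specific with partial coverage. Such loci still overlap a
  true specific region.
- Diagnostic SNPs taken from the donor scaffold flanks may include
  donor-private variants; they discriminate the panel's donor correctly
  but need not be universal across all cultivars. The in-silico panel
  validation mirrors, but cannot replace, multi-cultivar wet-lab
  verification.
- The KASP thermodynamics are reduced to primer Tm and the 3'-clamp; no
  competition kinetics, tail hybridisation or rox normalisation is
  modelled.
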
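# alienmark

Design and validation of chromosome-arm-specific markers for alien
introgression breeding.

When a chromosome (or chromosome arm) from a wild or cultivated relative —
the *alien donor*, classically rye (*Secale cereale*, RR, 2n = 14) — is
transferred into a host crop such as bread wheat, breeders need cheap,
universal markers to trace that alien chromatin through crossing schemes.
`alienmark` implements the whole discovery funnel as a tested, reusable
library and CLI:

1. **Reduced-representation locus extraction** — in-silico RsaI (`GT^AC`)
   digestion, 464–494 bp size selection, clustering of fragments into loci
   at >90% identity.
2. **Alien-specificity filtering** — keep loci whose best local alignment
   to the host scores below 0.5 (identity × query coverage), then
   intersect across donor cultivars to retain only conserved,
   *universal* alien-specific sequences.
3. **PCR marker design and placement** — primer design, in-silico PCR with
   a 3'-clamp mismatch policy, and the three-step panel logic: amplifies
   in every cultivar but not the host → in exactly one disomic addition
   line (chromosome) → in exactly one corresponding ditelosomic addition
   line (arm); verified on a second, independent panel.
4. **KASP conversion** — anchor each placed locus to donor scaffolds, find
   the single diagnostic SNP with clean 40–120 bp host-consistent flanks,
   and emit a co-dominant assay: two allele-specific primers differing
   only at the 3'-terminal base, carrying the universal FAM
   (`gaaggtgaccaagttcatgct`) and HEX (`gaaggtcggagtcaacggatt`) tails, plus
   one common primer.
5. **Endpoint genotype calling** — NTC gating and spherical clustering of
   the FAM/HEX plane into `A1A1` (alien), `A2A2` (host), `A1A2`
   (carrier) and `no_call`, with screen summaries (in hemizygous screens
   a carrier of one alien arm reads heterozygous).

A synthetic-data module generates host and cultivar genomes, complete
disomic/ditelosomic addition-line panels and fluorescence plates with an
exact truth table, so every stage is testable without external data. The
package also ships a published 14-assay rye chromosome-arm KASP panel
(1RS–7RL) as machine-readable data for the validator.

## Worked example

Run the funnel on a compact simulated study (3 donor chromosomes of
120 kb, five discovery cultivars plus one held-out donor):

```sh
cat > config.yaml <<EOF
simulation:
  seed: 7
  n_alien_chromosomes: 3
  chromosome_length: 120000
  alien_specific_region_rate: 70.0
  alien_specific_region_length: [3000, 5000]
EOF
alienmark run --config config.yaml --outdir runs/demo
```

prints the funnel, one count per stage:

```
fragments: 7214
fragments_in_window: 110
loci: 102
specific_loci: 42
conserved_specific: 8
markers_designed: 8
universal_markers: 8
chromosome_assigned: 8
arm_assigned: 8
second_panel_validated: 8
kasp_assays: 5
kasp_valid: 5
kasp_arms: 5
```

Read: 7,214 restriction fragments across the five cultivars, 110 inside
the size window, clustered into 102 loci of which 42 had <50% host
homology; 8 of those were conserved across all five cultivars, and all 8
yielded universal PCR markers that the addition-line panel placed on a
single chromosome arm each. Five of them (covering five of the six
simulated arms) converted into valid, panel-discriminating KASP assays.
`runs/demo/` then contains the stage products — `loci.tsv`,
`homology.tsv`, `conserved.fa`, `markers.tsv`, `matrix.tsv`,
`assignments.tsv`, `kasp_table.tsv` — plus `truth.tsv` (the planted
regions), a config snapshot and a checksum manifest; rerunning with the
same config reproduces the manifest bit-exactly. An emitted assay looks
exactly like a vendor order sheet:

```
assay_id  arm  primer_role  sequence
KM0001    3RS  F            gaaggtgaccaagttcatgctGCTCGGGCTTCTTGAGC
KM0001    3RS  H            gaaggtcggagtcaacggattGCTCGGGCTTCTTGAGG
KM0001    3RS  C            TAGGGTAGGATGCCTGACAG
```

Individual stages are available as subcommands (`simulate`, `digest`,
`cluster`, `filter`, `design-pcr`, `matrix`, `assign`, `design-kasp`,
`validate-kasp`, `genotype`, `summarize`) and as plain library functions
(`alienmark.digest`, `alienmark.call_genotypes`, ...).

## Documentation

`docs/methods.md` describes the underlying models, parameter defaults and
their rationale, what the simulator does and does not emulate, and known
limitations.
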
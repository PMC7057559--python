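"""KASP assay construction: anchoring, diagnostic SNP calling (vs a
brute-force window oracle), tailed primer building and table validation."""

import random

import pytest

from alienmark.genome import Genome
from alienmark.kasp import (
    TAIL_FAM,
    TAIL_HEX,
    DiagnosticSNP,
    KASPAssay,
    KaspPrimerConfig,
    anchor_to_scaffolds,
    build_kasp_assay,
    bundled_rye_panel,
    call_diagnostic_snps,
    insilico_kasp_genotype,
    load_kasp_table,
    validate_kasp_table,
    write_kasp_table,
)

from conftest import random_dna


def _mutate_at(seq, pos, rng=None):
    rng = rng or random.Random(pos)
    return seq[:pos] + rng.choice([b for b in "ACGT" if b != seq[pos]]) + seq[pos + 1 :]


class TestAnchor:
    def test_verbatim_substring_is_unique(self):
        scaffold = random_dna(8_000, seed=70)
        locus = scaffold[3_000:3_480]
        anchor = anchor_to_scaffolds(locus, Genome("s", {"sc1": scaffold}))
        assert anchor.unique
        assert anchor.scaffold_id == "sc1"
        assert anchor.identity == 1.0
        assert locus in anchor.expanded_sequence

    def test_duplicated_locus_is_not_unique(self):
        locus = random_dna(480, seed=71)
        filler = random_dna(2_000, seed=72)
        scaffold = filler + locus + filler[::-1] + locus + filler
        anchor = anchor_to_scaffolds(locus, Genome("s", {"sc1": scaffold}))
        assert not anchor.unique

    def test_no_hit_reports_zero_identity(self):
        anchor = anchor_to_scaffolds(
            random_dna(480, seed=73), Genome("s", {"sc1": random_dna(5_000, seed=74)})
        )
        assert not anchor.unique and anchor.identity == 0.0


class TestDiagnosticSNPs:
    def test_single_mismatch_with_clean_flanks(self):
        host_seq = random_dna(2_000, seed=80)
        alien = _mutate_at(host_seq, 1_000)
        host = Genome("host", {"h1": host_seq})
        snps = call_diagnostic_snps(alien, host)
        assert len(snps) == 1
        snp = snps[0]
        assert snp.position == 1_000
        assert snp.alien_allele == alien[1_000]
        assert snp.host_allele == host_seq[1_000]
        assert alien[1_000 - len(snp.left_flank) : 1_000] == snp.left_flank
        assert alien[1_001 : 1_001 + len(snp.right_flank)] == snp.right_flank
        assert snp.flank_host_identity == 1.0

    def test_close_mismatch_pair_rejected(self):
        host_seq = random_dna(1_000, seed=81)
        alien = _mutate_at(_mutate_at(host_seq, 500), 510)
        assert call_diagnostic_snps(alien, Genome("host", {"h1": host_seq})) == []

    def test_accepted_set_matches_window_oracle(self):
        """Planted SNP spacings vs an exhaustive brute-force window check."""
        min_flank = 40
        planted = [30, 300, 360, 500, 530, 800, 2000, 2960]
        host_seq = random_dna(3_000, seed=82)
        alien = host_seq
        for p in planted:
            alien = _mutate_at(alien, p)
        snps = call_diagnostic_snps(alien, Genome("host", {"h1": host_seq}))
        # oracle: a planted SNP is acceptable iff every other mismatch and
        # both sequence ends are more than min_flank columns away
        expected = {
            p
            for p in planted
            if p >= min_flank
            and p <= len(alien) - 1 - min_flank
            and all(abs(p - q) > min_flank for q in planted if q != p)
        }
        assert {s.position for s in snps} == expected == {300, 360, 800, 2000}

    def test_indel_adjacent_mismatch_excluded(self):
        host_seq = random_dna(2_000, seed=83)
        # alien: delete 3 bases at 1000, mismatches 20 bp and 300 bp downstream
        alien = host_seq[:1_000] + host_seq[1_003:]
        alien = _mutate_at(alien, 1_020)
        alien = _mutate_at(alien, 1_300)
        snps = call_diagnostic_snps(alien, Genome("host", {"h1": host_seq}))
        assert {s.position for s in snps} == {1_300}

    def test_no_homolog_gives_empty_list(self):
        alien = random_dna(1_000, seed=84)
        host = Genome("host", {"h1": random_dna(5_000, seed=85)})
        assert call_diagnostic_snps(alien, host) == []


class TestBuildAssay:
    def _snp(self, seed=91, left=120, right=120):
        rng = random.Random(seed)
        lf, rf = random_dna(left, rng=rng), random_dna(right, rng=rng)
        return DiagnosticSNP(
            locus_id="L1", position=left, alien_allele="A", host_allele="G",
            left_flank=lf, right_flank=rf, flank_host_identity=1.0,
        )

    def test_structure_and_round_trip_validation(self):
        assay = build_kasp_assay(self._snp(), arm="3RS")
        assert assay.allele1_primer.startswith(TAIL_FAM)
        assert assay.allele2_primer.startswith(TAIL_HEX)
        assert assay.allele1_core[:-1] == assay.allele2_core[:-1]
        assert (assay.allele1_core[-1], assay.allele2_core[-1]) == ("A", "G")
        report = validate_kasp_table([assay])
        assert report.n_valid == 1 and report.n_arms == 1 and not report.failures

    def test_short_flank_exhausts_primer_window(self):
        snp = self._snp(left=20)
        cfg = KaspPrimerConfig(allele_min_length=25)
        with pytest.raises(ValueError, match="primer window exhausted"):
            build_kasp_assay(snp, arm="3RS", cfg=cfg)

    def test_swapped_tails_flagged(self):
        assay = build_kasp_assay(self._snp(), arm="1RL")
        swapped = KASPAssay(
            assay_id=assay.assay_id, arm=assay.arm,
            allele1_primer=TAIL_HEX + assay.allele1_core,
            allele2_primer=TAIL_FAM + assay.allele2_core,
            common_primer=assay.common_primer, alleles=assay.alleles,
        )
        report = validate_kasp_table([swapped])
        assert report.failures == [(assay.assay_id, "tail mismatch")]

    def test_internal_variant_flagged(self):
        assay = build_kasp_assay(self._snp(), arm="1RL")
        core = assay.allele2_core
        corrupt = "T" + core[1:] if core[0] != "T" else "G" + core[1:]
        broken = KASPAssay(
            assay_id="bad", arm="1RL",
            allele1_primer=assay.allele1_primer,
            allele2_primer=TAIL_HEX + corrupt,
            common_primer=assay.common_primer, alleles=assay.alleles,
        )
        report = validate_kasp_table([broken])
        assert report.failures == [("bad", "non-terminal variant")]

    def test_table_round_trip(self, tmp_path):
        assays = [build_kasp_assay(self._snp(seed=s), arm=arm)
                  for s, arm in ((91, "3RS"), (92, "6RL"))]
        path = tmp_path / "kasp.tsv"
        write_kasp_table(assays, path)
        back = load_kasp_table(path)
        assert [(a.assay_id, a.arm, a.allele1_primer, a.common_primer) for a in back] == [
            (a.assay_id, a.arm, a.allele1_primer, a.common_primer) for a in assays
        ]


class TestBundledPanel:
    def test_panel_is_complete_and_valid(self):
        assays = bundled_rye_panel()
        report = validate_kasp_table(assays)
        assert len(assays) == 14
        assert report.n_valid == 14
        assert report.n_arms == 14

    def test_known_assay_alleles(self):
        by_id = {a.assay_id: a for a in bundled_rye_panel()}
        assert by_id["SWK28002"].alleles == ("A", "G")
        assert by_id["SWK28002"].allele1_core == "CGGACAATGCACGATCGA"
        assert by_id["SWK252224"].alleles == ("C", "A")
        assert by_id["SWK252224"].allele1_core == "TCAACACCAAGAGAAGGGAAC"


class TestInsilicoGenotype:
    def test_codominant_discrimination_by_construction(self):
        host_seq = random_dna(3_000, seed=95)
        alien_seq = _mutate_at(host_seq, 1_500)
        host = Genome("host", {"h1": host_seq})
        snps = call_diagnostic_snps(alien_seq, host)
        snp = next(s for s in snps if s.position == 1_500)
        assay = build_kasp_assay(snp, arm="5RL")
        alien = Genome("alien", {"1R": alien_seq})
        addition = Genome("add", {"h1": host_seq, "1R": alien_seq})
        assert insilico_kasp_genotype(assay, host) == "A2A2"
        assert insilico_kasp_genotype(assay, alien) == "A1A1"
        assert insilico_kasp_genotype(assay, addition) == "A1A2"
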
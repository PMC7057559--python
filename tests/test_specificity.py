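"""Host-homology scoring and cross-cultivar intersection."""

import random

import pytest

from alienmark.digestion import SLAFLocus
from alienmark.genome import Genome
from alienmark.specificity import (
    filter_specific,
    homology_to_host,
    homology_reports,
    intersect_cultivars,
)

from conftest import random_dna


def _locus(seq, locus_id="L1", cultivar="cv"):
    return SLAFLocus(locus_id=locus_id, cultivar=cultivar, sequence=seq)


def smith_waterman_best(query: str, target: str, match=2, mismatch=-3,
                        gap_open=5, gap_extend=2):
    """Brute-force affine-gap Smith-Waterman; returns (identity, coverage)
    of the optimal local alignment.  Independent test oracle."""
    n, m = len(query), len(target)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    trace = {}
    best, best_cell = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + (match if query[i - 1] == target[j - 1] else mismatch)
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > 0:
                if H[i][j] == diag:
                    trace[(i, j)] = (i - 1, j - 1, query[i - 1] == target[j - 1])
                elif H[i][j] == F[i][j]:
                    trace[(i, j)] = (i - 1, j, None)
                else:
                    trace[(i, j)] = (i, j - 1, None)
            if H[i][j] > best:
                best, best_cell = H[i][j], (i, j)
    if best_cell is None:
        return 0.0, 0.0
    matches = columns = 0
    i, j = best_cell
    qend = i
    while (i, j) in trace and H[i][j] > 0:
        pi, pj, is_match = trace[(i, j)]
        columns += 1
        if is_match:
            matches += 1
        i, j = pi, pj
    qstart = i
    identity = matches / columns if columns else 0.0
    coverage = (qend - qstart) / n
    return identity, coverage


class TestHomology:
    def test_exact_substring_is_not_specific(self):
        host_seq = random_dna(5_000, seed=21)
        locus = _locus(host_seq[1000:1480])
        rep = homology_to_host(locus, Genome("host", {"h1": host_seq}))
        assert rep.identity == 1.0
        assert rep.coverage == 1.0
        assert rep.score == 1.0
        assert not rep.is_specific
        assert rep.hit == ("h1", 1000, 1480)

    def test_random_locus_agrees_with_smith_waterman_oracle(self):
        """A random locus vs an unrelated host: both the blast-based score
        and the brute-force local-alignment oracle put homology far below
        the 0.5 specificity threshold and agree on the classification."""
        rng = random.Random(33)
        host_seq = random_dna(3_000, rng=rng)
        locus_seq = random_dna(480, rng=rng)
        rep = homology_to_host(_locus(locus_seq), Genome("host", {"h1": host_seq}))
        sw_identity, sw_coverage = smith_waterman_best(locus_seq, host_seq)
        assert rep.is_specific
        assert rep.score < 0.5 and sw_identity * sw_coverage < 0.5
        assert abs(rep.score - sw_identity * sw_coverage) < 0.25

    def test_diverged_copy_agrees_with_oracle_score(self):
        """A 97%-identical full-length copy: blast score and the SW oracle
        agree closely and both call it non-specific."""
        rng = random.Random(5)
        host_seq = random_dna(4_000, rng=rng)
        sub = list(host_seq[500:980])
        for p in rng.sample(range(480), 14):
            sub[p] = rng.choice([b for b in "ACGT" if b != sub[p]])
        locus_seq = "".join(sub)
        rep = homology_to_host(_locus(locus_seq), Genome("host", {"h1": host_seq}))
        sw_identity, sw_coverage = smith_waterman_best(locus_seq, host_seq)
        assert not rep.is_specific
        assert abs(rep.score - sw_identity * sw_coverage) < 0.05

    def test_empty_host_rejected(self):
        with pytest.raises(ValueError):
            homology_to_host(_locus("ACGT" * 100), Genome("host", {}))


class TestFilterSpecific:
    def test_threshold_zero_drops_everything(self):
        host = Genome("host", {"h1": random_dna(2_000, seed=2)})
        loci = [_locus(random_dna(480, seed=i), f"L{i}") for i in range(3)]
        assert filter_specific(loci, host, threshold=0.0) == []

    def test_monotone_in_threshold(self):
        rng = random.Random(8)
        host_seq = random_dna(5_000, rng=rng)
        loci = []
        for i in range(6):
            if i % 2:
                loci.append(_locus(random_dna(480, rng=rng), f"L{i}"))
            else:
                loci.append(_locus(host_seq[i * 700 : i * 700 + 480], f"L{i}"))
        host = Genome("host", {"h1": host_seq})
        kept_low = {l.locus_id for l in filter_specific(loci, host, 0.3)}
        kept_high = {l.locus_id for l in filter_specific(loci, host, 0.9)}
        assert kept_low <= kept_high

    def test_threshold_one_drops_only_perfect_hits(self):
        host_seq = random_dna(3_000, seed=13)
        perfect = _locus(host_seq[100:580], "perfect")
        rand = _locus(random_dna(480, seed=77), "rand")
        host = Genome("host", {"h1": host_seq})
        kept = filter_specific([perfect, rand], host, threshold=1.0)
        assert [l.locus_id for l in kept] == ["rand"]


class TestIntersectCultivars:
    def _loci(self, seqs, cultivar):
        return [_locus(s, f"{cultivar}_L{i}", cultivar) for i, s in enumerate(seqs)]

    def test_shared_locus_is_conserved(self):
        shared = random_dna(480, seed=4)
        per = {c: self._loci([shared], c) for c in ("a", "b", "c")}
        out = intersect_cultivars(per)
        assert len(out) == 1
        assert out[0].sequence == shared
        assert set(out[0].members) == {"a", "b", "c"}
        assert out[0].min_pairwise_identity == 1.0

    def test_locus_missing_from_one_cultivar_is_excluded(self):
        shared = random_dna(480, seed=4)
        only_a = random_dna(480, seed=5)
        per = {
            "a": self._loci([shared, only_a], "a"),
            "b": self._loci([shared], "b"),
        }
        out = intersect_cultivars(per)
        assert len(out) == 1 and out[0].sequence == shared

    def test_empty_cultivar_gives_empty_result(self):
        per = {"a": self._loci([random_dna(480, seed=1)], "a"), "b": []}
        assert intersect_cultivars(per) == []

    def test_symmetric_under_reordering(self):
        rng = random.Random(6)
        shared = [random_dna(480, rng=rng) for _ in range(3)]
        noise = lambda c: [random_dna(480, rng=rng) for _ in range(2)]
        per = {c: self._loci(shared + noise(c), c) for c in ("a", "b", "c")}
        fwd = intersect_cultivars(per)
        rev = intersect_cultivars(dict(reversed(per.items())))
        assert {frozenset(c.members.values()) for c in fwd} == {
            frozenset(c.members.values()) for c in rev
        }

    def test_five_cultivar_result_within_four_cultivar_result(self, small_run):
        """Adding a cultivar can only shrink the conserved set."""
        per = small_run.specific_by_cultivar
        full = intersect_cultivars(per)
        subset = intersect_cultivars({c: per[c] for c in list(per)[:4]})
        full_ids = {c.members[list(per)[0]] for c in full}
        subset_ids = {c.members[list(per)[0]] for c in subset}
        assert full_ids <= subset_ids
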
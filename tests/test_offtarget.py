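"""Off-target matcher: brute-force oracle, seeded matcher, BLAST adapter."""

import numpy as np
import pytest

from asrnadesign.design import DesignParams, TargetWindow, design_asrna, reverse_complement
from asrnadesign.genome_io import Genome
from asrnadesign.offtarget import (
    OfftargetHit,
    ScreenParams,
    brute_force_scan,
    classify_hit,
    find_matches,
    lossless_seed_length,
    parse_blast_tabular,
    run_external_blast,
)
from asrnadesign.synthetic import SyntheticGenomeSpec, make_genome


def _random_genome(rng, length, topology="linear"):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    return Genome(id="rand", sequence=seq, topology=topology)


def _hit_key(h):
    return (h.subject_start, h.subject_end, h.subject_strand,
            round(h.identity, 6), h.aligned_length)


class TestBruteForceScan:
    def test_planted_unique_21mer_found_exactly_once(self):
        rng = np.random.default_rng(42)
        genome = _random_genome(rng, 5000)
        pos = 1234
        probe = genome.sequence[pos : pos + 21]
        hits = brute_force_scan(probe, genome, ScreenParams())
        full = [h for h in hits if h.aligned_length == 21 and h.identity == 100.0]
        assert any(h.subject_start == pos and h.subject_strand == +1 for h in full)

    def test_reverse_complement_probe_hits_same_locus_minus_strand(self):
        rng = np.random.default_rng(43)
        genome = _random_genome(rng, 5000)
        pos = 2000
        probe = reverse_complement(genome.sequence[pos : pos + 21])
        hits = brute_force_scan(probe, genome, ScreenParams())
        assert any(
            h.subject_start == pos and h.subject_strand == -1 and h.identity == 100.0
            for h in hits
        )

    def test_strict_thresholds_reduce_to_exact_substring_search(self):
        rng = np.random.default_rng(44)
        genome = _random_genome(rng, 3000)
        probe = genome.sequence[500:521]
        params = ScreenParams(min_identity=100.0, min_match_length=21,
                              seed_word_size=11)
        hits = brute_force_scan(probe, genome, params)
        # naive oracle: exact occurrences on either strand
        expected = set()
        rc = reverse_complement(probe)
        for i in range(len(genome) - 20):
            if genome.sequence[i : i + 21] == probe:
                expected.add((i, +1))
            if genome.sequence[i : i + 21] == rc:
                expected.add((i, -1))
        assert {(h.subject_start, h.subject_strand) for h in hits} == expected

    def test_all_n_probe_matches_nothing(self):
        rng = np.random.default_rng(45)
        genome = _random_genome(rng, 2000)
        assert brute_force_scan("N" * 21, genome, ScreenParams()) == []

    def test_every_hit_satisfies_the_thresholds(self):
        genome = make_genome(
            SyntheticGenomeSpec(
                n_genes=6, seed=19, duplicate_pairs=[(2, "whole_gene_with_flanks")]
            )
        )
        params = ScreenParams(min_identity=85.0, min_match_length=16)
        probe = genome.sequence[100:121]
        for h in brute_force_scan(probe, genome, params):
            assert h.aligned_length >= 16
            assert h.identity >= 85.0


class TestFindMatches:
    def test_clean_fixture_yields_only_the_intended_site(self, clean_genome):
        params = ScreenParams()
        dparams = DesignParams()
        for feat in clean_genome.cds_features:
            d = design_asrna(clean_genome, feat, dparams)
            hits = find_matches(d, clean_genome, params)
            assert len(hits) == 1
            (h,) = hits
            assert h.is_intended
            assert h.identity == 100.0 and h.aligned_length == 21
            assert (h.subject_start, h.subject_end) == (
                d.window.genomic_start,
                d.window.genomic_end,
            )

    def test_duplicated_gene_gains_one_offtarget(self, full_dup_genome):
        dparams = DesignParams()
        feat = full_dup_genome.cds_features[0]
        d = design_asrna(full_dup_genome, feat, dparams)
        hits = find_matches(d, full_dup_genome, ScreenParams())
        assert len(hits) == 2
        assert sum(h.is_intended for h in hits) == 1
        off = next(h for h in hits if not h.is_intended)
        assert off.identity == 100.0 and off.aligned_length == 21

    def test_intended_site_always_found(self):
        genome = make_genome(
            SyntheticGenomeSpec(n_genes=10, seed=31, fraction_minus_strand=0.5)
        )
        dparams = DesignParams()
        for params in (
            ScreenParams(),
            ScreenParams(min_identity=100.0, min_match_length=21),
            ScreenParams(min_identity=60.0, min_match_length=12, seed_word_size=8),
        ):
            for feat in genome.cds_features:
                d = design_asrna(genome, feat, dparams)
                hits = find_matches(d, genome, params)
                assert any(h.is_intended for h in hits)

    @pytest.mark.parametrize(
        "params",
        [
            ScreenParams(),
            ScreenParams(min_identity=90.0, min_match_length=18),
            ScreenParams(min_identity=70.0, min_match_length=12, seed_word_size=7),
            ScreenParams(min_identity=100.0, min_match_length=21),
        ],
        ids=["default", "strict", "loose", "exact-only"],
    )
    def test_oracle_equivalence_on_duplicated_genomes(self, params):
        dparams = DesignParams()
        for seed in (61, 62):
            genome = make_genome(
                SyntheticGenomeSpec(
                    n_genes=8,
                    gene_length=200,
                    seed=seed,
                    fraction_minus_strand=0.4,
                    duplicate_pairs=[(0, "sd_start_region"),
                                     (1, "whole_gene_with_flanks")],
                )
            )
            for feat in genome.cds_features:
                d = design_asrna(genome, feat, dparams)
                builtin = find_matches(d, genome, params)
                oracle = brute_force_scan(d.target_sense_seq, genome, params)
                assert [_hit_key(h) for h in builtin] == [_hit_key(h) for h in oracle]

    def test_strand_symmetry_of_the_screen(self):
        genome = make_genome(SyntheticGenomeSpec(n_genes=5, seed=77))
        glen = len(genome)
        mirrored = Genome(
            id=genome.id,
            sequence=reverse_complement(genome.sequence),
            topology=genome.topology,
        )
        probe = genome.sequence[200:221]
        params = ScreenParams()
        fwd = brute_force_scan(probe, genome, params)
        rev = brute_force_scan(probe, mirrored, params)
        mirror = {
            (glen - h.subject_end, glen - h.subject_start, -h.subject_strand)
            for h in rev
        }
        assert {
            (h.subject_start, h.subject_end, h.subject_strand) for h in fwd
        } == mirror

    def test_circular_genome_finds_origin_spanning_duplicate(self):
        rng = np.random.default_rng(9)
        core = _random_genome(rng, 400).sequence
        probe = core[50:71]
        # place a second copy across the origin: last 10 nt + first 11 nt
        seq = probe[10:] + core[11:390] + probe[:10]
        genome = Genome(id="circ", sequence=seq, topology="circular")
        hits = brute_force_scan(probe, genome, ScreenParams())
        wrapped = [h for h in hits if h.subject_end > len(genome)]
        assert any(h.identity == 100.0 and h.aligned_length == 21 for h in wrapped)


class TestLosslessSeed:
    def test_bound_shrinks_with_looser_identity(self):
        assert lossless_seed_length(21, 100.0, 21) == 21
        assert lossless_seed_length(15, 80.0, 21) == 3
        # at 90% identity the minimum sits at l=20: e=2 mismatches cut the
        # alignment into 3 runs, the longest at least ceil(18/3) = 6
        assert lossless_seed_length(15, 90.0, 21) == 6

    def test_bound_is_never_below_one(self):
        assert lossless_seed_length(10, 50.0, 21) >= 1


class TestClassifyHit:
    def _hit(self, start, end, strand=+1, contig="toy"):
        return OfftargetHit("g", 1, contig, start, end, strand, end - start, 100.0, 0)

    def test_identical_interval_is_intended(self):
        w = TargetWindow("toy", 100, 121, +1, -8)
        assert classify_hit(self._hit(100, 121), w)

    def test_other_contig_is_offtarget(self):
        w = TargetWindow("toy", 100, 121, +1, -8)
        assert not classify_hit(self._hit(100, 121, contig="other"), w)

    def test_adjacent_interval_zero_overlap_is_offtarget(self):
        w = TargetWindow("toy", 100, 121, +1, -8)
        assert not classify_hit(self._hit(121, 142), w)
        assert classify_hit(self._hit(120, 141), w)  # 1 bp overlap

    def test_wrong_strand_is_offtarget(self):
        w = TargetWindow("toy", 100, 121, +1, -8)
        assert not classify_hit(self._hit(100, 121, strand=-1), w)

    def test_circular_overlap_through_the_origin(self):
        w = TargetWindow("circ", 390, 411, +1, -8)  # wraps a 400 nt genome
        assert classify_hit(self._hit(0, 15, contig="circ"), w, genome_length=400)


class TestExternalBlast:
    def test_backends_agree_on_planted_duplicate(self, full_dup_genome):
        dparams = DesignParams()
        params = ScreenParams(backend="external_blast")
        designs = [
            design_asrna(full_dup_genome, f, dparams)
            for f in full_dup_genome.cds_features
        ]
        blast_hits = run_external_blast(designs, full_dup_genome, params)
        for d in (designs[0], designs[-1]):  # the duplicated pair
            mine = {
                (h.subject_start, h.subject_end, h.subject_strand, h.is_intended)
                for h in find_matches(d, full_dup_genome, params)
            }
            theirs = {
                (h.subject_start, h.subject_end, h.subject_strand, h.is_intended)
                for h in blast_hits
                if h.locus_tag == d.locus_tag
            }
            assert mine == theirs
            assert any(not intended for *_, intended in theirs)

    def test_backends_agree_on_clean_fixture(self, clean_genome):
        dparams = DesignParams()
        params = ScreenParams(backend="external_blast")
        designs = [
            design_asrna(clean_genome, f, dparams) for f in clean_genome.cds_features
        ]
        hits = run_external_blast(designs, clean_genome, params)
        assert all(h.is_intended for h in hits)
        assert {h.locus_tag for h in hits} == {d.locus_tag for d in designs}
        assert all(h.identity == 100.0 and h.aligned_length == 21 for h in hits)
        assert all(h.evalue is not None for h in hits)

    def test_malformed_tabular_line_is_named(self):
        good = "q\ts\t100.0\t21\t0\t0\t1\t21\t10\t30\t1e-9\t40.1"
        assert parse_blast_tabular(good)[0]["length"] == 21
        with pytest.raises(ValueError, match="line 2"):
            parse_blast_tabular(good + "\nq\ts\tbroken")
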
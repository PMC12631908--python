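"""Satellite monomer discovery, HOR decomposition, copy quantification,
centromere delineation and morphology."""

import numpy as np
import pytest

from satkit.io_formats import GenomeRecord, revcomp
from satkit.satellite import (SatelliteMonomer, call_centromeres,
                              classify_morphology, decompose_hor,
                              discover_monomer, quantify_copies)
from satkit.synthetic import (ChromosomeSpec, GenomeSpec, SatelliteSpec,
                              generate_genome, substream)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _flank(rng, n=20_000):
    return _random_seq(rng, n)


class TestDiscoverMonomer:
    def test_default_array_yields_42bp_monomer(self, default_genome):
        genome, _ = default_genome
        monomers = discover_monomer(genome)
        assert monomers and monomers[0].length == 42

    def test_exact_30mer_consensus_up_to_rotation(self, rng):
        unit = _random_seq(rng, 30)
        seq = _flank(rng) + unit * 100 + _flank(rng)
        monomers = discover_monomer([GenomeRecord("c", seq)], min_copies=50)
        assert monomers and monomers[0].length == 30
        consensus = monomers[0].consensus
        # brute-force check over all cyclic rotations of the implanted unit
        rotations = {unit[i:] + unit[:i] for i in range(30)}
        assert consensus in rotations
        assert monomers[0].mean_identity > 0.99

    def test_low_complexity_rejected(self, rng):
        seq = _flank(rng) + "A" * 5000 + _flank(rng)
        monomers = discover_monomer([GenomeRecord("c", seq)])
        assert all(set(m.consensus) != {"A"} for m in monomers)

    def test_no_candidate_returns_empty(self, rng):
        monomers = discover_monomer([GenomeRecord("c", _random_seq(rng, 60_000))])
        assert monomers == []

    def test_recovery_over_seeds(self):
        """Monomer length and HOR period recovery across generator seeds."""
        hits = 0
        for seed in range(20):
            spec = GenomeSpec(chromosomes=[ChromosomeSpec(
                "chr1", 150_000, 0.5, satellite=SatelliteSpec(), te=None)],
                seed=seed)
            genome, truth = generate_genome(spec)
            monomers = discover_monomer(genome)
            if not monomers or monomers[0].length != 42:
                continue
            iv = max(monomers[0].arrays, key=len)
            hor = decompose_hor(genome[0].seq[iv.start:iv.end], monomers[0])
            if hor.hor_period == 4:
                hits += 1
        assert hits >= 19  # >= 95% of 20 seeds


class TestDecomposeHor:
    def test_default_array_period_and_variants(self, default_genome):
        genome, truth = default_genome
        t = truth.chromosomes["chr1"]
        array = genome[0].seq[t.satellite_array.start:t.satellite_array.end]
        monomers = discover_monomer(genome)
        hor = decompose_hor(array, monomers[0])
        assert hor.hor_period == 4
        assert hor.hor_consensus_length == 168
        assert len(hor.variant_unit_indices) == 2
        assert not hor.degenerate

    def test_identical_monomers_period_one(self, rng):
        unit = _random_seq(rng, 40)
        mono = SatelliteMonomer(unit, 40, 100, 1.0)
        hor = decompose_hor(unit * 100, mono)
        assert hor.hor_period == 1
        assert hor.variant_unit_indices == ()

    def test_alternating_classes_period_two(self, rng):
        a = _random_seq(rng, 40)
        b = a[:10] + ("A" if a[10] != "A" else "C") + a[11:]
        array = (a + b) * 60
        mono = SatelliteMonomer(a, 40, 120, 1.0)
        hor = decompose_hor(array, mono)
        assert hor.hor_period == 2

        # brute-force period of the class string confirms minimality
        classes = hor.unit_classes
        def explained(k):
            tot = 0
            for j in range(k):
                col = classes[j::k]
                vals, counts = np.unique(col, return_counts=True)
                tot += counts.max()
            return tot / len(classes)
        assert explained(1) < 0.9 and explained(2) >= 0.9

    def test_degenerate_array_flagged(self, rng):
        mono = SatelliteMonomer(_random_seq(rng, 40), 40, 100, 1.0)
        hor = decompose_hor(_random_seq(rng, 4000), mono)
        assert hor.degenerate

    def test_short_array_rejected(self, rng):
        mono = SatelliteMonomer(_random_seq(rng, 40), 40, 100, 1.0)
        with pytest.raises(ValueError, match="20 monomer"):
            decompose_hor(_random_seq(rng, 400), mono)


def brute_force_tiling(seq, consensus, min_identity):
    """Exhaustive sliding-window identity oracle with greedy tiling."""
    p = len(consensus)
    rc = revcomp(consensus)
    count = 0
    i = 0
    while i <= len(seq) - p:
        window = seq[i:i + p]
        ident = max(sum(a == b for a, b in zip(window, consensus)),
                    sum(a == b for a, b in zip(window, rc))) / p
        if ident >= min_identity:
            count += 1
            i += p
        else:
            i += 1
    return count


class TestQuantifyCopies:
    def test_exact_implant_counted_exactly(self, rng):
        unit = _random_seq(rng, 42)
        seq = _flank(rng) + unit * 500 + _flank(rng)
        genome = [GenomeRecord("c1", seq), GenomeRecord("c2", _random_seq(rng, 30_000))]
        mono = SatelliteMonomer(unit, 42, 500, 1.0)
        hits = quantify_copies(genome, mono, min_identity=0.96)
        assert hits["c1"].count == 500
        assert hits["c2"].count == 0

    def test_mutated_implant_matches_oracle_and_recovers(self, rng):
        unit = _random_seq(rng, 42)
        copies = []
        for _ in range(500):
            c = list(unit)
            for j in range(42):
                if rng.random() < 0.02:
                    c[j] = rng.choice([b for b in "ACGT" if b != c[j]])
            copies.append("".join(c))
        seq = _flank(rng, 5000) + "".join(copies) + _flank(rng, 5000)
        mono = SatelliteMonomer(unit, 42, 500, 0.98)
        # identity 0.90 tolerates the 2% mutation process (<= 4 mismatches)
        hits = quantify_copies([GenomeRecord("c", seq)], mono, min_identity=0.90)
        assert hits["c"].count == brute_force_tiling(seq, unit, 0.90)
        assert abs(hits["c"].count - 500) <= 10  # within 2% of the implant

    def test_reverse_strand_copies_found(self, rng):
        unit = _random_seq(rng, 42)
        seq = _flank(rng, 3000) + revcomp(unit * 50) + _flank(rng, 3000)
        mono = SatelliteMonomer(unit, 42, 50, 1.0)
        hits = quantify_copies([GenomeRecord("c", seq)], mono, min_identity=0.96)
        assert hits["c"].count == 50
        assert set(hits["c"].strands) == {"-"}

    def test_empty_genome(self):
        mono = SatelliteMonomer("ACGT" * 10, 40, 0, 1.0)
        assert quantify_copies([], mono) == {}

    def test_counts_non_increasing_in_identity(self, default_genome):
        genome, truth = default_genome
        mono = SatelliteMonomer(truth.monomer, 42, 0, 1.0)
        counts = [sum(h.count for h in quantify_copies(genome, mono, t).values())
                  for t in (0.85, 0.90, 0.96, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_oracle_equivalence_on_default_array(self, default_genome):
        genome, truth = default_genome
        t = truth.chromosomes["chr1"]
        sub = GenomeRecord("sub", genome[0].seq[t.satellite_array.start - 2000:
                                                t.satellite_array.end + 2000])
        mono = SatelliteMonomer(truth.monomer, 42, 0, 1.0)
        hits = quantify_copies([sub], mono, min_identity=0.96)
        assert hits["sub"].count == brute_force_tiling(sub.seq, truth.monomer, 0.96)


class TestCallCentromeres:
    @staticmethod
    def _calls(genome, monomer, **kw):
        hits = quantify_copies(genome, monomer, min_identity=0.96)
        return hits, call_centromeres(genome, hits, monomer.length, **kw)

    def test_called_interval_matches_truth(self, default_genome, discovered_monomer):
        genome, truth = default_genome
        _, calls = self._calls(genome, discovered_monomer)
        for rec in genome:
            t = truth.chromosomes[rec.id].satellite_array
            call = calls[rec.id]
            assert call.called
            inter = max(0, min(call.interval.end, t.end) - max(call.interval.start, t.start))
            union = max(call.interval.end, t.end) - min(call.interval.start, t.start)
            assert inter / union >= 0.9

    def test_two_arrays_largest_called_secondary_warned(self, rng):
        unit = _random_seq(rng, 42)
        big = unit * 500       # 21 kb
        small = unit * 120     # 5 kb
        seq = (_random_seq(rng, 50_000) + small + _random_seq(rng, 100_000)
               + big + _random_seq(rng, 50_000))
        genome = [GenomeRecord("c", seq)]
        mono = SatelliteMonomer(unit, 42, 0, 1.0)
        hits = quantify_copies(genome, mono)
        calls = call_centromeres(genome, hits, 42)
        call = calls["c"]
        big_start = 50_000 + len(small) + 100_000
        assert call.called
        assert abs(call.interval.start - big_start) < 1000
        assert len(call.secondary_blocks) == 1

    def test_satellite_free_chromosome_uncalled(self, rng):
        genome = [GenomeRecord("c", _random_seq(rng, 100_000))]
        mono = SatelliteMonomer(_random_seq(rng, 42), 42, 0, 1.0)
        hits = quantify_copies(genome, mono)
        call = call_centromeres(genome, hits, 42)["c"]
        assert not call.called
        assert call.interval is None

    def test_window_halving_stability(self, default_genome, discovered_monomer):
        genome, _ = default_genome
        _, calls10 = self._calls(genome, discovered_monomer, window=10_000)
        _, calls5 = self._calls(genome, discovered_monomer, window=5_000)
        for chrom in calls10:
            a, b = calls10[chrom].interval, calls5[chrom].interval
            assert abs(a.start - b.start) < 2 * 10_000
            assert abs(a.end - b.end) < 2 * 10_000


class TestMorphology:
    @staticmethod
    def _call(short_mb, long_mb):
        from satkit.satellite import CentromereCall
        from satkit.io_formats import Interval
        s, l = int(short_mb * 1e6), int(long_mb * 1e6)
        return CentromereCall("c", True,
                              Interval("c", s, s + 100), 1,
                              short_arm=s, long_arm=l,
                              ls_ratio=(l / s if s else float("inf")))

    @pytest.mark.parametrize("short,long,expected", [
        (15, 15, "metacentric"),       # midpoint at 50%: ratio 1.0
        (7.5, 22.5, "submetacentric"),  # midpoint at 25%: ratio 3.0
        (5, 25, "subtelocentric"),      # ratio 5
        (1, 30, "acrocentric"),         # ratio 30
    ])
    def test_levan_classes(self, short, long, expected):
        assert classify_morphology(self._call(short, long)) == expected

    def test_zero_short_arm_is_telocentric(self):
        call = self._call(1, 30)
        call.short_arm, call.ls_ratio = 0, float("inf")
        assert classify_morphology(call) == "telocentric"

    def test_uncalled_rejected(self):
        from satkit.satellite import CentromereCall
        with pytest.raises(ValueError):
            classify_morphology(CentromereCall("c", called=False))
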
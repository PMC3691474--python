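"""Genomic-island detection: outlier channels and island calling."""

import numpy as np
import pytest

from hgtclock.composition import GCProfile, codon_position_gc, dinucleotide_profile
from hgtclock.island_scan import (
    IslandConfig,
    call_islands,
    flag_bias_windows,
    flag_gc_outliers,
    islands_to_bed,
    islands_to_tsv,
    scan_genome,
    window_deltas,
)
from hgtclock.seq_io import CdsFeature
from hgtclock.synthetic_data import simulate_genome, simulate_hgt_event


def _gene(i, gc, contig="c1"):
    feat = CdsFeature(f"g{i:03d}", contig, 1 + 1000 * i, 900 + 1000 * i, "+")
    prof = GCProfile(gc, gc, gc, 300)
    return feat, prof


def _gc_cloud(rng, n=100, mean=0.38, sd=0.035):
    return [
        _gene(i, float(np.clip(rng.normal(mean, sd), 0, 1))) for i in range(n)
    ]


class TestFlagGcOutliers:
    def test_uniform_genome_unflagged(self):
        genes = [_gene(i, 0.38) for i in range(20)]
        # zero spread: every gene sits exactly on the center
        assert not flag_gc_outliers(genes).any()

    def test_two_sd_rule(self, rng):
        """A 47% gene violates the 2-SD band around 38 +/- 3.5; 44% does not."""
        genes = _gc_cloud(rng) + [_gene(100, 0.47), _gene(101, 0.44)]
        flags = flag_gc_outliers(genes)
        assert flags[100]
        assert not flags[101]

    def test_classical_background_matches_moments(self, rng):
        genes = _gc_cloud(rng) + [_gene(100, 0.47)]
        cfg = IslandConfig(robust=False)
        flags = flag_gc_outliers(genes, cfg)
        assert flags[100]

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            flag_gc_outliers([_gene(i, 0.38) for i in range(5)])


def _markov_seq(n, rng):
    """First-order Markov chain with strong CpG/TpA depletion, GC ~ 0.4."""
    base = np.array([0.3, 0.2, 0.2, 0.3])
    T = np.tile(base, (4, 1))
    T[1, 2] *= 0.05  # C -> G
    T[3, 0] *= 0.05  # T -> A
    T /= T.sum(axis=1, keepdims=True)
    s = [rng.choice(4, p=base)]
    for _ in range(n - 1):
        s.append(rng.choice(4, p=T[s[-1]]))
    return "".join("ACGT"[i] for i in s)


def _iid_seq(n, rng):
    return "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=n))


class TestFlagBiasWindows:
    def test_window_count_bookkeeping(self, rng):
        seqs = [_iid_seq(600, rng) for _ in range(20)]
        gp = dinucleotide_profile("".join(seqs))
        assert window_deltas(seqs, gp, 8).size == 20 - 8 + 1

    def test_fewer_genes_than_window_rejected(self, rng):
        seqs = [(_gene(i, 0.4)[0], _iid_seq(600, rng)) for i in range(4)]
        gp = dinucleotide_profile("".join(s for _, s in seqs))
        with pytest.raises(ValueError):
            flag_bias_windows(seqs, gp)

    def test_null_flag_rate_bounded(self, rng):
        """One composition model: at the classical 2-SD cut, at most 5% of
        windows flag; at the default cut, none should."""
        genes = [(_gene(i, 0.4)[0], _iid_seq(600, rng)) for i in range(100)]
        gp = dinucleotide_profile("".join(s for _, s in genes))
        deltas = window_deltas([s for _, s in genes], gp, 8)
        classical_rate = (
            deltas > deltas.mean() + 2.0 * deltas.std(ddof=1)
        ).mean()
        assert classical_rate <= 0.05
        assert not flag_bias_windows(genes, gp).any()

    def test_planted_bias_insert_recovered(self, rng):
        """A 10-gene insert from a different dinucleotide model (same G+C)
        is flagged; the host background is not."""
        host = [_iid_seq(600, rng) for _ in range(60)]
        insert = [_markov_seq(600, rng) for _ in range(10)]
        seqs = host[:30] + insert + host[30:]
        genes = [(_gene(i, 0.4)[0], s) for i, s in enumerate(seqs)]
        gp = dinucleotide_profile("".join(seqs))
        flags = flag_bias_windows(genes, gp)
        assert flags[30:40].all()
        assert not flags[:23].any() and not flags[47:].any()


class TestCallIslands:
    def test_no_flags_no_islands(self):
        genes = [_gene(i, 0.38) for i in range(20)]
        z = np.zeros(20, dtype=bool)
        assert call_islands(z, z, genes) == []

    def test_gap_rule_splits_runs(self):
        genes = [_gene(i, 0.38) for i in range(20)]
        hot = np.zeros(20, dtype=bool)
        hot[2:8] = True   # 6 hot
        hot[11:17] = True  # 6 hot, separated by 3 cold genes
        calls = call_islands(hot, np.zeros_like(hot), genes)
        assert len(calls) == 2
        assert calls[0].locus_tags == tuple(f"g{i:03d}" for i in range(2, 8))

    def test_single_gap_absorbed(self):
        genes = [_gene(i, 0.38) for i in range(20)]
        hot = np.zeros(20, dtype=bool)
        hot[2:6] = True
        hot[7:10] = True  # one cold gene inside
        calls = call_islands(hot, np.zeros_like(hot), genes)
        assert len(calls) == 1
        assert len(calls[0].locus_tags) == 8  # span includes the gap gene

    def test_min_run_enforced(self):
        genes = [_gene(i, 0.38) for i in range(20)]
        hot = np.zeros(20, dtype=bool)
        hot[2:6] = True  # only 4 hot genes
        assert call_islands(hot, np.zeros_like(hot), genes) == []

    def test_flag_channels_recorded(self):
        genes = [_gene(i, 0.38) for i in range(20)]
        gc = np.zeros(20, dtype=bool)
        bias = np.zeros(20, dtype=bool)
        gc[2:8] = True
        bias[5:11] = True
        [call] = call_islands(gc, bias, genes)
        assert call.flags == frozenset({"gc", "bias"})

    def test_misaligned_vectors_rejected(self):
        genes = [_gene(i, 0.38) for i in range(20)]
        with pytest.raises(ValueError):
            call_islands(np.zeros(19, bool), np.zeros(20, bool), genes)


def _triples(g):
    by = {cs.locus_tag: cs for cs in g.codon_sequences}
    return [
        (f, codon_position_gc(by[f.locus_tag]), by[f.locus_tag].nucleotides)
        for f in g.features
    ]


class TestScanGenome:
    def test_planted_island_recovered(self, host_params):
        host = simulate_genome(60, 0.35, seed=5, gene_length_dist=200)
        g = simulate_hgt_event(host, 0.62, 12, 0.0, host_params, seed=6)
        tags = set(g.truth.parameters["operon_locus_tags"])
        calls = scan_genome(_triples(g), g.record.sequence)
        assert len(calls) == 1
        assert len(tags & set(calls[0].locus_tags)) >= 6

    def test_determinism(self, host_params):
        host = simulate_genome(40, 0.35, seed=7, gene_length_dist=200)
        a = scan_genome(_triples(host), host.record.sequence)
        b = scan_genome(_triples(host), host.record.sequence)
        assert a == b

    def test_threshold_monotonicity(self, host_params):
        """Lowering the G+C threshold never removes flagged coverage."""
        host = simulate_genome(60, 0.35, seed=8, gene_length_dist=200)
        g = simulate_hgt_event(host, 0.62, 12, 0.0, host_params, seed=9)
        trip = _triples(g)
        spans = {}
        for thr in (2.0, 2.5):
            calls = scan_genome(trip, g.record.sequence,
                                IslandConfig(gc_sd_threshold=thr))
            spans[thr] = set().union(*[set(c.locus_tags) for c in calls]) if calls else set()
        assert spans[2.5] <= spans[2.0]


def test_reports_round_trip(tmp_path, host_params):
    host = simulate_genome(60, 0.35, seed=5, gene_length_dist=200)
    g = simulate_hgt_event(host, 0.62, 12, 0.0, host_params, seed=6)
    calls = scan_genome(_triples(g), g.record.sequence)
    bed, tsv = tmp_path / "i.bed", tmp_path / "i.tsv"
    islands_to_bed(calls, bed)
    islands_to_tsv(calls, tsv)
    bed_line = bed.read_text().splitlines()[0].split("\t")
    tsv_line = tsv.read_text().splitlines()[1].split("\t")
    # BED is 0-based half-open, TSV 1-based inclusive: same interval
    assert int(bed_line[1]) + 1 == int(tsv_line[1])
    assert int(bed_line[2]) == int(tsv_line[2])
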
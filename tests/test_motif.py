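import numpy as np
import pytest

from tfcohort import motif, synthetic
from tfcohort.motif import (
    PWM,
    Promoter,
    PromoterSet,
    background_density,
    build_propensity_table,
    count_sites,
    extract_promoter_windows,
    match_scan,
    read_pwm_transfac,
    target_propensity,
    write_pwm_transfac,
)


def revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@pytest.fixture(scope="module")
def regulator():
    reg, _ = synthetic.make_regulator_pwm(1, 1)
    return reg


class TestPwmModel:
    def test_degenerate_matrix_info_and_core(self):
        # one dominant base per position: information maximal everywhere,
        # core defaults to the first window under the tie rule
        counts = np.zeros((10, 4))
        counts[:, 2] = 100
        pwm = PWM("deg", counts)
        assert np.allclose(pwm.info, pwm.info[0])
        assert pwm.core_start == 0

    def test_frequencies_normalised(self, regulator):
        np.testing.assert_allclose(regulator.freqs.sum(axis=1), 1.0)
        assert (regulator.freqs > 0).all()

    def test_regulator_core_in_informative_region(self, regulator):
        # the non-N positions are 2-9 (1-based): the 5-wide core must sit there
        assert 1 <= regulator.core_start <= 4

    def test_core_adapts_to_short_matrices(self):
        pwm = PWM("short", np.eye(4)[:3] * 50)
        assert pwm.core_length == 3
        assert pwm.core_start == 0
        with pytest.raises(ValueError, match="empty"):
            PWM("empty", np.empty((0, 4)))


class TestTransfacRoundTrip:
    def test_counts_survive_write_read(self, tmp_path, regulator):
        _, decoys = synthetic.make_regulator_pwm(1, 2)
        path = tmp_path / "matrices.transfac"
        write_pwm_transfac([regulator, *decoys], path)
        back = read_pwm_transfac(path)
        assert [m.id for m in back] == [regulator.id] + [d.id for d in decoys]
        for orig, new in zip([regulator, *decoys], back):
            np.testing.assert_allclose(orig.counts, new.counts)

    def test_malformed_file_reports_failure(self, tmp_path):
        bad = tmp_path / "bad.transfac"
        bad.write_text("AC  M1\nXX\nP0 A C G T\n01 banana\n//\n")
        with pytest.raises(ValueError):
            read_pwm_transfac(bad)


class TestMatchScan:
    def test_consensus_word_scores_mss_one(self, regulator):
        prom = Promoter("g", "p", regulator.consensus)
        hits = match_scan(prom, regulator)
        assert any(h.mss == pytest.approx(1.0) and h.strand == "+" for h in hits)

    def test_reverse_complement_hits_minus_strand(self, regulator):
        prom = Promoter("g", "p", revcomp(regulator.consensus))
        hits = match_scan(prom, regulator)
        top = max(hits, key=lambda h: h.mss)
        assert top.strand == "-"
        assert top.mss == pytest.approx(1.0)
        assert top.offset == 0

    def test_toy_matrix_matches_hand_computed_mss(self):
        # 3-position matrix, frequencies chosen by hand (pseudocount 0 via
        # large counts keeps arithmetic transparent)
        counts = np.array([
            [80.0, 10.0, 5.0, 5.0],
            [5.0, 80.0, 10.0, 5.0],
            [5.0, 5.0, 10.0, 80.0],
        ])
        pwm = PWM("toy", counts, mss_cutoff=0.0, css_cutoff=0.0,
                  pseudocount=1.0)

        def hand_score(word):
            total = 0.0
            for i, b in enumerate(word):
                total += pwm.info[i] * pwm.freqs[i, "ACGT".index(b)]
            smin = sum(pwm.info[i] * pwm.freqs[i].min() for i in range(3))
            smax = sum(pwm.info[i] * pwm.freqs[i].max() for i in range(3))
            return (total - smin) / (smax - smin)

        seq = "ACTGA"
        # core window covers all 3 positions, so only MSS needs checking
        plus_hits = {h.offset: h.mss for h in match_scan(Promoter("g", "p", seq),
                                                         pwm) if h.strand == "+"}
        for off in range(3):
            assert plus_hits[off] == pytest.approx(hand_score(seq[off:off + 3]))

    def test_scores_bounded_on_random_sequence(self, regulator, rng):
        seq = "".join(rng.choice(list("ACGT"), 500))
        pwm = PWM(regulator.id, regulator.counts, mss_cutoff=0.0, css_cutoff=0.0)
        hits = match_scan(Promoter("g", "p", seq), pwm)
        assert hits, "cutoff 0 must report every offset"
        for h in hits:
            assert 0.0 <= h.mss <= 1.0
            assert 0.0 <= h.css <= 1.0

    def test_n_bases_degrade_but_do_not_invalidate(self, regulator):
        word = regulator.consensus
        hits = match_scan(Promoter("g", "p", word[:4] + "N" + word[5:]),
                          PWM(regulator.id, regulator.counts, mss_cutoff=0.0,
                              css_cutoff=0.0))
        full = match_scan(Promoter("g", "p", word),
                          PWM(regulator.id, regulator.counts, mss_cutoff=0.0,
                              css_cutoff=0.0))
        assert max(h.mss for h in hits) < max(h.mss for h in full)

    def test_short_promoter_returns_empty(self, regulator):
        assert match_scan(Promoter("g", "p", "ACGT"), regulator) == []

    def test_lowering_cutoff_never_decreases_counts(self, regulator, rng):
        seq = "".join(rng.choice(list("ACGT"), 600))
        prom = PromoterSet([Promoter("g", "p", seq)])
        loose = PWM(regulator.id, regulator.counts, mss_cutoff=0.6)
        tight = PWM(regulator.id, regulator.counts, mss_cutoff=0.8)
        assert count_sites(prom, loose)["p"] >= count_sites(prom, tight)["p"]


class TestSiteCounting:
    def test_no_hits_and_planted_consensus(self, regulator, rng):
        bg = "".join(rng.choice(list("ACGT"), 100))
        planted = regulator.consensus + bg[20:60] + regulator.consensus
        proms = PromoterSet([
            Promoter("g1", "p1", "A" * 50),
            Promoter("g2", "p2", planted),
        ])
        counts = count_sites(proms, regulator)
        assert counts["p1"] == 0
        assert counts["p2"] >= 2

    def test_hit_table_lists_every_passing_hit(self, regulator, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        proms = PromoterSet([Promoter("g1", "p1", seq),
                             Promoter("g2", "p2", regulator.consensus)])
        df = motif.hit_table(proms, regulator)
        counts = count_sites(proms, regulator)
        assert (df.groupby("promoter_id").size().reindex(counts.index)
                .fillna(0).astype(int) == counts).all()
        assert (df["mss"] >= regulator.mss_cutoff).all()

    def test_planted_sites_recovered_at_default_cutoffs(self, small_dataset):
        counts = count_sites(small_dataset.promoters,
                             small_dataset.regulator_pwm)
        planted = small_dataset.truth.planted_site_counts
        # every planted draw scores near the maximum, so recovery >= planting
        assert (counts.loc[planted.index] >= 0).all()
        assert counts.loc[planted.index].sum() >= planted.sum()


class TestBackgroundDensity:
    def test_hand_value(self):
        proms = PromoterSet([Promoter("a", "p1", "A" * 600),
                             Promoter("b", "p2", "C" * 600)])
        assert background_density(proms, {"p1": 3, "p2": 0}) == \
            pytest.approx(0.0025)

    def test_zero_counts_rejected(self):
        proms = PromoterSet([Promoter("a", "p1", "A" * 100)])
        with pytest.raises(ValueError, match="zero"):
            background_density(proms, {"p1": 0})

    def test_duplication_invariance(self):
        proms1 = PromoterSet([Promoter("a", "p1", "A" * 200)])
        proms2 = PromoterSet([Promoter("a", "p1", "A" * 200),
                              Promoter("b", "p2", "A" * 200)])
        assert background_density(proms1, {"p1": 4}) == \
            background_density(proms2, {"p1": 4, "p2": 4})


class TestTargetPropensity:
    def test_background_level_gene_scores_one(self):
        p = Promoter("g", "p", "A" * 600)
        rho = 4 / 600
        assert target_propensity([p], {"p": 4}, rho) == pytest.approx(1.0)

    def test_two_promoter_hand_value(self):
        ps = [Promoter("g", "p1", "A" * 600), Promoter("g", "p2", "C" * 600)]
        assert target_propensity(ps, {"p1": 6, "p2": 0}, 0.0025) == \
            pytest.approx(2.0)

    def test_global_scaling_invariance(self):
        ps = [Promoter("g", "p1", "A" * 300)]
        assert target_propensity(ps, {"p1": 2}, 0.01) == \
            pytest.approx(target_propensity(ps, {"p1": 6}, 0.03))

    def test_background_gene_expectation_near_one(self, small_tp):
        # across a genome of mostly background genes the mean tp is ~1
        assert abs(small_tp["tp"].mean() - 1.0) < 3 * small_tp["tp"].std() / \
            np.sqrt(len(small_tp))

    def test_ranks_are_permutation(self, small_tp):
        assert sorted(small_tp["tp_rank"]) == list(range(1, len(small_tp) + 1))

    def test_planted_to_background_ratio_with_specific_cutoffs(self):
        # at stringent cutoffs false-positive hits vanish, so the recovered
        # propensity ratio approaches the planted site-density ratio
        cfg = synthetic.SyntheticConfig(
            n_genes=400, n_targets=80, site_density_ratio=5.0,
            background_site_rate=0.008, promoter_len=1000,
            n_comparisons=1, n_groups=2,
            group_size=10, n_enriched_groups=1, seed=9)
        reg, _ = synthetic.make_regulator_pwm(cfg.seed, 1)
        promoters, truth = synthetic.generate_promoters(cfg, reg)
        strict = motif.PWM(reg.id, reg.counts, mss_cutoff=0.99,
                           css_cutoff=0.99)
        tp = build_propensity_table(promoters, strict)
        t = truth.target_flags
        tp_t = tp.loc[t[t].index, "tp"]
        tp_b = tp.loc[t[~t].index, "tp"]
        ratio = tp_t.mean() / tp_b.mean()
        se = ratio * np.sqrt(
            tp_t.var() / (tp_t.mean() ** 2 * len(tp_t))
            + tp_b.var() / (tp_b.mean() ** 2 * len(tp_b)))
        assert abs(ratio - cfg.site_density_ratio) < 3 * se


class TestPromoterWindows:
    @pytest.fixture()
    def genome(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGT"), 2000))
        fa = tmp_path / "genome.fa"
        fa.write_text(">chr1\n" + seq + "\n")
        return fa, seq

    def test_plus_strand_window(self, tmp_path, genome):
        fa, seq = genome
        bed = tmp_path / "tss.bed"
        bed.write_text("chr1\t1000\t1001\tgeneA\t0\t+\n")
        proms = extract_promoter_windows(bed, fa)
        assert proms.promoters[0].length == 600
        assert proms.promoters[0].sequence == seq[500:1100]

    def test_minus_strand_window_is_reverse_complement(self, tmp_path, genome):
        fa, seq = genome
        bed = tmp_path / "tss.bed"
        bed.write_text("chr1\t999\t1000\tgeneB\t0\t-\n")
        proms = extract_promoter_windows(bed, fa)
        expected = revcomp(seq[999 - 100 + 1:999 + 500 + 1])
        assert proms.promoters[0].sequence == expected

    def test_truncation_warns(self, tmp_path, genome, caplog):
        fa, _ = genome
        bed = tmp_path / "tss.bed"
        bed.write_text("chr1\t100\t101\tgeneC\t0\t+\n")
        import logging
        with caplog.at_level(logging.WARNING, logger="tfcohort.motif"):
            proms = extract_promoter_windows(bed, fa)
        assert proms.promoters[0].length == 200
        assert "truncated" in caplog.text
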
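"""Fused SSM scoring, database search, peak pairing, identification rate."""

import math

import numpy as np
import pytest

from thzssm import (
    CorpusTooSmallError,
    EmptyPeakListError,
    SsmWeights,
    builtin_table1,
    generate_replicates,
    identification_rate,
    pair_peaks,
    search,
    ssm_accuracy,
)
from thzssm.io import table1_rows
from thzssm.types import DatabaseEntry, Peak, PeakList, SpectralDatabase, Spectrum

EXPECTED_PAIR_COUNTS = {
    "fentanyl": 6, "methoxyacetylfentanyl": 3, "acetylfentanyl": 3,
    "furanylfentanyl": 5, "butyrylfentanyl": 3, "4-fluoroisobutyrfentanyl": 3,
    "carfentanil": 4, "valerylfentanyl": 3,
}


class TestSsmWeights:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SsmWeights(0.3, 0.8)

    def test_weights_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            SsmWeights(-0.2, 1.2)


class TestPairPeaks:
    @pytest.mark.parametrize("analyte", sorted(EXPECTED_PAIR_COUNTS))
    def test_full_pairing_per_analog(self, table1, analyte):
        pairing = pair_peaks(table1[analyte].dft, table1[analyte].experimental)
        assert len(pairing.pairs) == EXPECTED_PAIR_COUNTS[analyte]
        assert pairing.unmatched_dft == []
        assert pairing.unmatched_exp == []

    def test_shifts_reproduce_tabulated_values(self, table1):
        """Every arithmetically consistent tabulated shift is reproduced
        exactly; the one inconsistent row (butyrylfentanyl 0.56/0.52, printed
        0.01 but 0.56-0.52=0.04) is excluded and its recomputed value checked."""
        computed = {}
        for analyte, pair in table1.items():
            for d, e, s in pair_peaks(pair.dft, pair.experimental).pairs:
                computed[(analyte, round(d, 2))] = s
        n_consistent = 0
        for row in table1_rows():
            got = computed[(row.analyte, row.dft_freq)]
            assert got == pytest.approx(row.dft_freq - row.exp_freq, abs=1e-12)
            if abs((row.dft_freq - row.exp_freq) - row.shift) < 5e-3:
                assert got == pytest.approx(row.shift, abs=5e-3)
                n_consistent += 1
        assert n_consistent == 29  # all rows except butyrylfentanyl 0.56
        assert computed[("butyrylfentanyl", 0.56)] == pytest.approx(0.04)

    def test_fentanyl_first_pair_shift(self, table1):
        pairing = pair_peaks(table1["fentanyl"].dft, table1["fentanyl"].experimental)
        by_dft = {round(d, 2): (e, s) for d, e, s in pairing.pairs}
        assert by_dft[0.85] == (pytest.approx(0.92), pytest.approx(-0.07))

    def test_valerylfentanyl_zero_shift_pair(self, table1):
        pairing = pair_peaks(
            table1["valerylfentanyl"].dft, table1["valerylfentanyl"].experimental
        )
        assert (0.91, 0.91, 0.0) in [(d, e, round(s, 12)) for d, e, s in pairing.pairs]

    def test_empty_experimental_list_fully_unmatched(self, table1):
        empty = PeakList("fentanyl", "experimental", [])
        pairing = pair_peaks(table1["fentanyl"].dft, empty)
        assert pairing.pairs == []
        assert len(pairing.unmatched_dft) == 6
        assert pairing.unmatched_exp == []

    def test_out_of_tolerance_peaks_stay_unmatched(self):
        dft = PeakList("t", "dft", [Peak(1.0, 1.0), Peak(2.0, 1.0)])
        exp = PeakList("t", "experimental", [Peak(1.05, 1.0), Peak(2.5, 1.0)])
        pairing = pair_peaks(dft, exp, tolerance=0.15)
        assert [(round(d, 2), round(e, 2)) for d, e, _ in pairing.pairs] == [(1.0, 1.05)]
        assert pairing.unmatched_dft == [2.0]
        assert pairing.unmatched_exp == [2.5]


class TestSsmAccuracy:
    @pytest.mark.parametrize("alpha", [0.0, 0.2, 0.37, 1.0])
    def test_self_match_scores_one_and_ranks_first(self, clean_db, alpha):
        w = SsmWeights(alpha, 1.0 - alpha)
        for name in clean_db.names:
            entry = clean_db[name]
            result = search(entry.spectrum, clean_db, w, target_peaks=entry.peaks)
            assert result.top_hit.name == name
            assert result.top_hit.acc == pytest.approx(1.0, abs=1e-12)

    def test_pure_shape_weights_reproduce_cosine_ranking(self, clean_db):
        entry = clean_db["MF"]
        scores = ssm_accuracy(
            entry.spectrum, entry.peaks, clean_db, SsmWeights(1.0, 0.0)
        )
        by_acc = sorted(scores, key=lambda n: -scores[n].acc)
        by_cs = sorted(scores, key=lambda n: -scores[n].shape)
        assert by_acc == by_cs

    def test_toy_corpus_matches_hand_computation(self):
        """Acc on a 3-entry corpus equals an independent arithmetic evaluation
        of alpha*CS + beta*(1 - DFD/sum DFD)."""
        grid = 0.5 + 0.3 * np.arange(11)
        rng = np.random.default_rng(7)
        curves = {name: rng.uniform(0.1, 1.0, size=11) for name in "ABC"}
        peaklists = {
            "A": [Peak(0.8, 0.4), Peak(2.0, 1.0)],
            "B": [Peak(1.1, 0.6), Peak(2.6, 0.3)],
            "C": [Peak(0.8, 0.2), Peak(1.7, 0.9), Peak(3.2, 0.5)],
        }
        db = SpectralDatabase({
            n: DatabaseEntry(Spectrum(n, grid, curves[n]),
                             PeakList(n, "experimental", peaklists[n]))
            for n in "ABC"
        })
        ty = rng.uniform(0.1, 1.0, size=11)
        target = Spectrum("t", grid.copy(), ty)
        tpeaks = PeakList("t", "experimental", [Peak(0.9, 0.5), Peak(2.1, 0.8)])
        w = SsmWeights(0.2, 0.8)
        got = ssm_accuracy(target, tpeaks, db, w)

        # independent arithmetic oracle
        def cos(u, v):
            num = math.fsum(x * y for x, y in zip(u, v))
            return num / (math.hypot(*u) * math.hypot(*v))

        def fp(peaks):
            mx = max(p.intensity for p in peaks)
            return [((p.freq - 0.5) / 3.0, p.intensity / mx) for p in peaks]

        def frechet(P, Q):
            best = [float("inf")]
            m, n = len(P), len(Q)

            def walk(i, j, cur):
                cur = max(cur, math.dist(P[i], Q[j]))
                if cur >= best[0]:
                    return
                if i == m - 1 and j == n - 1:
                    best[0] = cur
                    return
                if i + 1 < m:
                    walk(i + 1, j, cur)
                if j + 1 < n:
                    walk(i, j + 1, cur)
                if i + 1 < m and j + 1 < n:
                    walk(i + 1, j + 1, cur)

            walk(0, 0, 0.0)
            return best[0]

        dfds = {n: frechet(fp(peaklists[n]), fp(tpeaks.peaks)) for n in "ABC"}
        total = sum(dfds.values())
        for n in "ABC":
            expected = 0.2 * cos(curves[n], ty) + 0.8 * (1 - dfds[n] / total)
            assert got[n].acc == pytest.approx(expected, abs=1e-12)

    def test_feature_terms_sum_to_n_minus_one(self, clean_db):
        entry = clean_db["CF"]
        jittered = PeakList(
            "CF", "experimental",
            [Peak(p.freq + 0.01, p.intensity * 0.9) for p in entry.peaks],
        )
        scores = ssm_accuracy(entry.spectrum, jittered, clean_db, SsmWeights(0.0, 1.0))
        total_dfd = sum(h.dfd for h in scores.values())
        assert total_dfd > 0
        feature_sum = sum(1.0 - h.dfd / total_dfd for h in scores.values())
        assert feature_sum == pytest.approx(len(clean_db) - 1, abs=1e-12)

    def test_accuracy_affine_in_alpha(self, clean_db):
        entry = clean_db["FF"]
        target = clean_db["BF"]
        accs = []
        for alpha in (0.2, 0.5, 0.8):
            scores = ssm_accuracy(
                target.spectrum, target.peaks, clean_db, SsmWeights(alpha, 1 - alpha)
            )
            accs.append(scores["FF"].acc)
        assert accs[1] == pytest.approx((accs[0] + accs[2]) / 2, abs=1e-12)

    def test_database_order_does_not_change_scores(self, clean_db):
        entry = clean_db["VF"]
        shuffled = SpectralDatabase(
            {n: clean_db.entries[n] for n in reversed(clean_db.names)},
        )
        a = ssm_accuracy(entry.spectrum, entry.peaks, clean_db)
        b = ssm_accuracy(entry.spectrum, entry.peaks, shuffled)
        for name in clean_db.names:
            assert a[name].acc == b[name].acc
        ra = search(entry.spectrum, clean_db, target_peaks=entry.peaks)
        rb = search(entry.spectrum, shuffled, target_peaks=entry.peaks)
        assert [h.name for h in ra] == [h.name for h in rb]

    def test_empty_target_peaks_rejected_with_hint(self, clean_db):
        entry = clean_db["FN"]
        empty = PeakList("FN", "experimental", [])
        with pytest.raises(EmptyPeakListError, match="find_peaks"):
            ssm_accuracy(entry.spectrum, empty, clean_db)

    def test_corpus_of_one_rejected(self, clean_db):
        entry = clean_db["FN"]
        single = SpectralDatabase({"FN": entry})
        with pytest.raises(CorpusTooSmallError):
            ssm_accuracy(entry.spectrum, entry.peaks, single)

    def test_degenerate_zero_total_dfd_gives_full_feature_term(self):
        grid = 0.5 + 0.3 * np.arange(11)
        pk = [Peak(1.0, 1.0), Peak(2.0, 0.5)]
        db = SpectralDatabase({
            n: DatabaseEntry(Spectrum(n, grid, y),
                             PeakList(n, "experimental", list(pk)))
            for n, y in (("A", np.linspace(0.1, 1, 11)), ("B", np.linspace(1, 0.1, 11)))
        })
        target = Spectrum("t", grid, np.linspace(0.1, 1, 11))
        scores = ssm_accuracy(target, PeakList("t", "experimental", list(pk)), db,
                              SsmWeights(0.0, 1.0))
        assert scores["A"].acc == pytest.approx(1.0)
        assert scores["B"].acc == pytest.approx(1.0)


class TestSearch:
    def test_noisy_replicate_identified_at_rank_one(self, clean_db):
        reps = generate_replicates(n_rep=1, jitter_freq_sd=0.01,
                                   noise_sd=0.01, seed=31)
        true, spectrum = [r for r in reps if r[0] == "FN"][0]
        result = search(spectrum, clean_db, SsmWeights(0.2, 0.8), preprocess=True)
        assert result.top_hit.name == "FN"

    def test_hits_sorted_descending(self, clean_db):
        entry = clean_db["AF"]
        result = search(entry.spectrum, clean_db, target_peaks=entry.peaks)
        accs = [h.acc for h in result]
        assert accs == sorted(accs, reverse=True)
        assert len(result) == 8


class TestIdentificationRate:
    def test_noiseless_replicates_all_identified(self, clean_db):
        rate = identification_rate(clean_db, 1, 0.0, SsmWeights(), seed=3,
                                   jitter_freq_sd=0.0, amp_jitter_frac=0.0)
        assert rate == 1.0

    def test_deterministic_for_fixed_seed(self, clean_db):
        kw = dict(replicates_per_analyte=2, noise_sd=0.02, w=SsmWeights(), seed=99)
        assert identification_rate(clean_db, **kw) == identification_rate(clean_db, **kw)

    def test_negative_noise_rejected(self, clean_db):
        with pytest.raises(ValueError):
            identification_rate(clean_db, 1, -0.1, SsmWeights(), seed=0)
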
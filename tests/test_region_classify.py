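"""Window classification signatures, region merging, and the rank-sum test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ztrscan import region_classify as rc
from ztrscan import synthetic_data as sd


def make_params(**kw):
    defaults = dict(lambda_bg_f=5.0, lambda_bg_m=5.0)
    defaults.update(kw)
    return rc.ClassifyParams(**defaults)


def window_pair(f_cov, m_cov, f_den, m_den, n=1, chrom="chrZ"):
    base = pd.DataFrame({
        "chrom": chrom, "start": np.arange(n) * 50_000,
        "end": (np.arange(n) + 1) * 50_000,
        "n_covered": 50_000, "excluded": False,
    })
    f = base.copy()
    f["norm_cov"] = f_cov
    f["snp_density_f"] = f_den
    m = base.copy()
    m["norm_cov"] = m_cov
    m["snp_density_m"] = m_den
    return f, m


class TestClassifyWindows:
    @pytest.mark.parametrize("f_cov,m_cov,f_den,m_den,label", [
        (1.0, 1.0, 100.0, 4.0, "ZTR"),          # female-only density elevation
        (0.5, 1.0, 5.0, 5.0, "HEMIZYGOUS_Z"),    # half female coverage
        (1.0, 2.0, 100.0, 100.0, "Z_DUP"),       # male doubled, both elevated
        (1.0, 1.0, 5.0, 5.0, "PAR"),             # full coverage, no elevation
        (1.0, 1.0, 5.0, 100.0, "UNCLASSIFIED"),  # male-only elevation fits nothing
    ])
    def test_signatures(self, f_cov, m_cov, f_den, m_den, label):
        f, m = window_pair(f_cov, m_cov, f_den, m_den)
        out = rc.classify_windows(f, m, make_params())
        assert out["label"].iloc[0] == label

    def test_baseline_chromosome_declared_autosomal(self):
        f, m = window_pair(1.0, 1.0, 5.0, 5.0, chrom="chrA")
        out = rc.classify_windows(f, m, make_params(), baseline_chroms={"chrA"})
        assert out["label"].iloc[0] == "AUTOSOME_LIKE"

    def test_mismatched_grids_rejected(self):
        f, m = window_pair(1.0, 1.0, 5.0, 5.0, n=2)
        m = m.iloc[::-1].reset_index(drop=True)
        m["start"] = [50_000, 0]
        with pytest.raises(ValueError):
            rc.classify_windows(f, m.assign(start=[999, 0]), make_params())

    def test_background_density_required(self):
        f, m = window_pair(1.0, 1.0, 5.0, 5.0)
        with pytest.raises(ValueError):
            rc.classify_windows(f, m, rc.ClassifyParams())


def test_elevation_rule_uses_max_of_fold_and_poisson_band():
    # lam=5: threshold max(15, 5+3*sqrt(5)) = 15
    assert not rc.is_elevated(14.9, 5.0)
    assert rc.is_elevated(15.0, 5.0)
    # lam=0.25: fold rule would give 0.75; Poisson band dominates (1.75)
    assert not rc.is_elevated(1.0, 0.25)
    assert rc.is_elevated(1.75, 0.25)


def labelled_frame(labels):
    n = len(labels)
    return pd.DataFrame({
        "chrom": "chrZ", "start": np.arange(n) * 50_000,
        "end": (np.arange(n) + 1) * 50_000, "n_covered": 50_000,
        "excluded": [l == "EXCLUDED" for l in labels],
        "f_norm_cov": 1.0, "m_norm_cov": 1.0,
        "f_density": 5.0, "m_density": 5.0, "label": labels,
    })


class TestMergeCalls:
    def test_run_of_three_ztr_windows_merges(self):
        calls = rc.merge_calls(
            labelled_frame(["HEMIZYGOUS_Z", "HEMIZYGOUS_Z", "ZTR", "ZTR", "ZTR",
                            "HEMIZYGOUS_Z"]),
            make_params(min_run=2))
        ztr = [c for c in calls if c.label == "ZTR"]
        assert len(ztr) == 1
        assert ztr[0].n_windows == 3
        assert (ztr[0].start, ztr[0].end) == (100_000, 250_000)

    def test_isolated_single_window_demoted(self):
        calls = rc.merge_calls(
            labelled_frame(["HEMIZYGOUS_Z", "HEMIZYGOUS_Z", "ZTR",
                            "HEMIZYGOUS_Z", "HEMIZYGOUS_Z"]),
            make_params(min_run=2))
        assert not [c for c in calls if c.label == "ZTR"]
        assert any(c.label == "UNCLASSIFIED" for c in calls)

    def test_interior_hemizygous_run_becomes_envelope_candidate(self):
        calls = rc.merge_calls(
            labelled_frame(["ZTR", "ZTR", "HEMIZYGOUS_Z", "HEMIZYGOUS_Z",
                            "HEMIZYGOUS_Z", "ZTR", "ZTR"]),
            make_params(min_run=2))
        assert len(calls) == 1
        c = calls[0]
        assert c.label == "ZTR" and c.n_windows == 7
        assert c.interior_candidates == [(100_000, 250_000)]

    def test_single_interior_excluded_window_bridged(self):
        calls = rc.merge_calls(
            labelled_frame(["ZTR", "ZTR", "EXCLUDED", "ZTR", "ZTR"]),
            make_params(min_run=2))
        assert len(calls) == 1
        assert calls[0].label == "ZTR" and calls[0].n_windows == 5


def test_noise_free_classification_recovers_truth(layouts):
    """Window stats set to their exact expectations reproduce planted labels."""
    chrz = layouts[0]
    labels_true = chrz.window_labels()
    n = len(labels_true)
    d, pi = 0.002, 1e-4
    w = chrz.window_size
    f_cov, m_cov, f_den, m_den = [], [], [], []
    for i, lab in enumerate(labels_true):
        mid = i * w + w // 2
        in_del = chrz.in_w_deletion(mid)
        f_c = sd.copy_number(lab, "female", in_del) / 2
        m_c = sd.copy_number(lab, "male") / 2
        f_cov.append(f_c)
        m_cov.append(m_c)
        extra_f = d * w if (lab == "ZTR" and not in_del) else 0.0
        extra_both = d * w if lab == "Z_DUP" else 0.0
        f_den.append(pi * w + extra_f + extra_both)
        m_den.append(pi * w + extra_both)
    f, m = window_pair(np.array(f_cov), np.array(m_cov),
                       np.array(f_den), np.array(m_den), n=n)
    params = make_params(lambda_bg_f=pi * w, lambda_bg_m=pi * w)
    out = rc.classify_windows(f, m, params)
    expected = ["HEMIZYGOUS_Z" if (lab == "ZTR" and chrz.in_w_deletion(i * w + w // 2))
                else lab for i, lab in enumerate(labels_true)]
    assert list(out["label"]) == expected


class TestRankSum:
    def test_exact_enumeration_textbook_case(self):
        u, p = rc.rank_sum_test([1, 2, 3], [4, 5, 6], "less")
        assert u == 0.0
        assert p == pytest.approx(1 / 20)

    def test_identical_samples_two_sided_p_one(self):
        _, p = rc.rank_sum_test([1, 2, 3], [1, 2, 3], "two-sided")
        assert p == 1.0

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning):
            _, p = rc.rank_sum_test([2, 2], [2, 2, 2])
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rc.rank_sum_test([], [1, 2])

    def test_exact_matches_scipy_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = rng.normal(size=int(rng.integers(3, 9)))
            b = rng.normal(size=int(rng.integers(3, 9)))
            for alt in ("two-sided", "greater", "less"):
                _, p = rc.rank_sum_test(a, b, alt)
                ref = stats.mannwhitneyu(a, b, alternative=alt, method="exact")
                assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_and_normal_agree_at_min_eight(self):
        """Both branches agree within 0.01 on tie-free samples of size 8."""
        rng = np.random.default_rng(4)
        for _ in range(40):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            u = rc._u_statistic(a, b)
            for alt in ("two-sided", "greater", "less"):
                pe = min(rc._exact_p(np.concatenate([a, b]), 8, u, alt), 1.0)
                pn = min(rc._normal_p(a, b, u, alt), 1.0)
                assert abs(pe - pn) < 0.01

    def test_large_unbalanced_falls_back_to_normal(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=5)
        b = rng.normal(size=300)
        _, p = rc.rank_sum_test(a, b)
        assert 0 < p <= 1


def test_synthetic_ztr_density_elevation_significant(small_run):
    """ZTR female densities beat the chromosome background at p < 1e-4."""
    assert small_run.rank_sum["ztr_female_vs_rest_female"] < 1e-4
    assert small_run.rank_sum["ztr_female_vs_ztr_male"] < 1e-4
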
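"""NG86 counting vs an independent oracle, branch polarization, percentiles,
expression profiling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from Bio.Data import CodonTable

from ztrscan import constraint_expression as ce
from ztrscan import synthetic_data as sd

AA = CodonTable.unambiguous_dna_by_id[1].forward_table
STOPS = set(CodonTable.unambiguous_dna_by_id[1].stop_codons)
SENSE = sorted(AA)


# --- independent brute-force oracle (kept deliberately naive) --------------

def oracle_syn_sites(codon):
    syn = 0
    for i, base in enumerate(codon):
        for b in "ACGT":
            if b == base:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if AA.get(alt) == AA[codon]:
                syn += 1
    return syn / 3


def oracle_path_counts(c1, c2):
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    all_paths = []
    for order in itertools.permutations(diffs):
        cur, steps, through_stop = c1, [], False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if nxt in STOPS:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        all_paths.append((through_stop, steps))
    usable = [s for bad, s in all_paths if not bad] or [s for _, s in all_paths]
    sd_ = nd_ = 0.0
    for steps in usable:
        for a, b in steps:
            if AA.get(a) is not None and AA.get(a) == AA.get(b):
                sd_ += 1
            else:
                nd_ += 1
    return sd_ / len(usable), nd_ / len(usable)


class TestNG86:
    def test_identical_sequences_all_zero(self):
        seq = "ATGCTGAAA"
        r = ce.ng86_pairwise(seq, seq)
        assert (r.sd, r.nd, r.dS, r.dN) == (0.0, 0.0, 0.0, 0.0)

    def test_site_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            s = "".join(rng.choice(SENSE, 60))
            t = "".join(rng.choice(SENSE, 60))
            r = ce.ng86_pairwise(s, t)
            assert r.S + r.N == pytest.approx(3 * 60)

    def test_counts_match_oracle_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = "".join(rng.choice(SENSE, 200))
            b = "".join(rng.choice(SENSE, 200))
            r = ce.ng86_pairwise(a, b)
            S = sd_ = nd_ = 0.0
            for i in range(0, 600, 3):
                ca, cb = a[i:i + 3], b[i:i + 3]
                S += (oracle_syn_sites(ca) + oracle_syn_sites(cb)) / 2
                s, n = oracle_path_counts(ca, cb)
                sd_ += s
                nd_ += n
            assert r.S == pytest.approx(S)
            assert r.sd == pytest.approx(sd_)
            assert r.nd == pytest.approx(nd_)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ce.ng86_pairwise("ATGTAA", "ATGAAA")

    def test_jukes_cantor_saturation_flagged(self):
        assert ce.jukes_cantor(0.8) is None
        assert ce.jukes_cantor(0.0) == 0.0
        p = 0.1
        assert ce.jukes_cantor(p) == pytest.approx(-0.75 * math.log(1 - 4 * p / 3))


class TestBranchRates:
    def test_single_synonymous_change_polarized_to_z(self):
        # W matches the outgroup; Z carries a synonymous CTG->CTA change
        aln = {"Z": "ATGCTA", "W": "ATGCTG", "outgroup": "ATGCTG"}
        rates = ce.branch_rates(aln)
        assert rates["Z"].sd == 1.0 and rates["Z"].nd == 0.0
        assert rates["W"].sd == 0.0 and rates["W"].nd == 0.0

    def test_all_three_differ_reported_unpolarized(self):
        aln = {"Z": "ATGCTA", "W": "ATGCTG", "outgroup": "ATGCTT"}
        rates = ce.branch_rates(aln)
        assert rates["Z"].unpolarized_codons == 1
        assert rates["Z"].sd == 0.0 and rates["W"].sd == 0.0

    def test_branch_counts_conserve_pairwise_differences(self):
        sim = sd.simulate_codon_alignment(
            400, {"outgroup": (0.05, 0.5), "Z": (0.02, 0.5), "W": (0.02, 0.2)},
            seed=9)
        rates = ce.branch_rates(sim.alignment)
        pair = ce.ng86_pairwise(sim.alignment["Z"], sim.alignment["W"])
        total_sd = rates["Z"].sd + rates["W"].sd + rates["unpolarized"].sd
        total_nd = rates["Z"].nd + rates["W"].nd + rates["unpolarized"].nd
        assert total_sd == pytest.approx(pair.sd)
        assert total_nd == pytest.approx(pair.nd)

    def test_zero_ds_reported_undefined_with_dn(self):
        # one nonsynonymous Z change, no synonymous ones
        aln = {"Z": "ATGGCT", "W": "ATGACT", "outgroup": "ATGACT"}
        rates = ce.branch_rates(aln)
        assert rates["Z"].dS == 0.0
        assert not rates["Z"].omega_defined
        assert rates["Z"].dN is not None and rates["Z"].dN > 0

    def test_omega_recovery_near_one(self):
        """Neutral simulation (omega=1) is recovered by the estimator."""
        ests = []
        for seed in range(6):
            sim = sd.simulate_codon_alignment(
                1500, {"outgroup": (0.05, 1.0), "Z": (0.05, 1.0), "W": (0.05, 1.0)},
                seed=seed)
            rates = ce.branch_rates(sim.alignment)
            for br in ("Z", "W"):
                if rates[br].omega_defined:
                    ests.append(rates[br].omega)
        assert abs(np.mean(ests) - 1.0) < 0.25


class TestHiPercentile:
    def test_spec_arithmetic(self):
        scores = {"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4, "q": 0.3}
        table, ecdf = ce.hi_percentile(scores, ["a", "b", "c", "d"], ["q"])
        assert table["percentile"].iloc[0] == 75.0

    def test_max_score_hits_hundred(self):
        scores = {"a": 0.1, "b": 0.9, "q": 0.9}
        table, _ = ce.hi_percentile(scores, ["a", "b"], ["q"])
        assert table["percentile"].iloc[0] == 100.0

    def test_matches_naive_counting_oracle(self):
        rng = np.random.default_rng(2)
        bg = {f"g{i}": float(rng.random()) for i in range(200)}
        queries = {f"q{i}": float(rng.random()) for i in range(10)}
        table, ecdf = ce.hi_percentile({**bg, **queries}, list(bg), list(queries))
        for row in table.itertuples():
            naive = 100 * sum(v <= row.score for v in bg.values()) / len(bg)
            assert row.percentile == pytest.approx(naive)
        assert ecdf["ecdf"].iloc[-1] == 1.0
        assert table.sort_values("score")["percentile"].is_monotonic_increasing

    def test_missing_query_reported(self):
        table, _ = ce.hi_percentile({"a": 0.5}, ["a"], ["ghost"])
        assert bool(table["missing"].iloc[0])

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            ce.hi_percentile({"q": 0.5}, [], ["q"])


def expr_rows(gene, species, tissue, sex, tpms):
    return [{"species": species, "tissue": tissue, "sex": sex,
             "replicate": i + 1, "gene": gene, "tpm": t}
            for i, t in enumerate(tpms)]


class TestExpressionProfile:
    def test_replicate_mean_and_log1p(self):
        table = pd.DataFrame(expr_rows("g", "sp", "gonad", "female", [2, 4]))
        matrix, _ = ce.expression_profile(table)
        val = matrix.loc["g", ("sp", "gonad", "female")]
        assert val == pytest.approx(math.log(4.0))

    def test_tenfold_ovary_bias_flagged_at_threshold_two(self):
        rows = expr_rows("g", "sp", "gonad", "female", [50, 50])
        for tissue in ("gonad", "brain"):
            rows += expr_rows("g", "sp", tissue, "male", [5, 5])
        rows += expr_rows("g", "sp", "brain", "female", [5, 5])
        _, bias = ce.expression_profile(pd.DataFrame(rows), bias_fold_threshold=2)
        assert bias["gonad_bias"].iloc[0]

    def test_absent_condition_is_blank_not_zero(self):
        rows = expr_rows("g1", "sp", "gonad", "female", [3])
        rows += expr_rows("g2", "sp", "brain", "male", [3])
        matrix, bias = ce.expression_profile(pd.DataFrame(rows))
        assert np.isnan(matrix.loc["g1", ("sp", "brain", "male")])
        flags = bias.set_index("gene")["gonad_bias"]
        assert flags.loc["g2"] is None  # no female-gonad condition for g2

    def test_negative_tpm_rejected(self):
        table = pd.DataFrame(expr_rows("g", "sp", "gonad", "female", [-1]))
        with pytest.raises(ValueError):
            ce.expression_profile(table)
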
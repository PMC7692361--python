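"""Pseudo-sequence construction, coordinate maps, deletion accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ztrscan import w_reconstruct as wr
from ztrscan.region_classify import RegionCall


def vtable(rows):
    df = pd.DataFrame(rows, columns=["pos", "ref", "alt"])
    df["chrom"] = "c"
    return df


class TestBuild:
    def test_snp_substitution(self):
        w = wr.build_w_pseudosequence("ACGT", (0, 4), vtable([(2, "C", "T")]))
        assert w.sequence == "ATGT"

    def test_insertion_lengthens(self):
        w = wr.build_w_pseudosequence("ACGT", (0, 4), vtable([(2, "C", "CAA")]))
        assert w.sequence == "ACAAGT"
        assert len(w.sequence) == 4 + 2

    def test_deletion_shortens_and_maps(self):
        w = wr.build_w_pseudosequence("ACGTACGT", (0, 8), vtable([(2, "CGT", "C")]))
        assert w.sequence == "ACACGT"
        assert w.coord_map.z_to_w(5) == 3  # post-deletion base shifts left by 2
        assert w.coord_map.z_to_w(2) is None  # removed base has no image

    def test_ref_mismatch_raises_with_position(self):
        with pytest.raises(ValueError, match="4"):
            wr.build_w_pseudosequence("ACGT", (0, 4), vtable([(4, "C", "T")]))

    def test_overlapping_variant_skipped_leftmost_wins(self):
        w = wr.build_w_pseudosequence(
            "ACGTACGT", (0, 8), vtable([(2, "CGT", "C"), (4, "T", "G")]))
        assert w.skipped_variants == 1
        assert w.sequence == "ACACGT"

    def test_length_bookkeeping_exact(self):
        rows = [(2, "C", "T"), (4, "T", "TGG"), (6, "CG", "C")]
        w = wr.build_w_pseudosequence("ACGTACGTAA", (0, 10), vtable(rows))
        signed = sum(len(a) - len(r) for _, r, a in rows)
        assert len(w.sequence) == 10 + signed


class TestLiftover:
    def test_identity_without_indels(self):
        w = wr.build_w_pseudosequence("ACGTACGT", (0, 8), vtable([(3, "G", "C")]))
        assert wr.liftover(w.coord_map, (0, 8)) == ((0, 8), "ok")

    def test_upstream_insertion_shifts_downstream(self):
        w = wr.build_w_pseudosequence("ACGTACGT", (0, 8), vtable([(2, "C", "CAA")]))
        assert wr.liftover(w.coord_map, (4, 8)) == ((6, 10), "ok")

    def test_interval_outside_envelope_rejected(self):
        w = wr.build_w_pseudosequence("ACGTACGT", (2, 6), vtable([]))
        with pytest.raises(ValueError):
            wr.liftover(w.coord_map, (0, 4))

    def test_deleted_and_partial_intervals(self):
        call = RegionCall("c", 0, 400, "ZTR", 8,
                          interior_candidates=[(100, 200)])
        dels = wr.call_w_deletions(call, min_run=2, window_size=50)
        cmap = wr.CoordMap(interval=(0, 400))
        assert wr.liftover(cmap, (120, 180), dels) == (None, "deleted")
        iv, status = wr.liftover(cmap, (50, 150), dels)
        assert status == "partial" and iv == (50, 100)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_roundtrip_mapping_identity_off_indels(self, seed):
        rng = np.random.default_rng(seed)
        L = 400
        seq = "".join(rng.choice(list("ACGT"), L))
        pos = np.sort(rng.choice(np.arange(5, L - 5), 6, replace=False))
        pos = pos[np.concatenate([[True], np.diff(pos) >= 8])]
        rows = []
        for p in pos:
            if rng.random() < 0.5:
                rows.append((int(p) + 1, seq[p:p + 3], seq[p]))
            else:
                rows.append((int(p) + 1, seq[p], seq[p] + "TT"))
        w = wr.build_w_pseudosequence(seq, (0, L), vtable(rows))
        affected = set()
        for p, r, a in rows:
            affected.update(range(p - 1, p - 1 + len(r)))
        for z in range(L):
            if z in affected:
                continue
            wpos = w.coord_map.z_to_w(z)
            assert wpos is not None
            assert w.sequence[wpos] == seq[z]


class TestDeletionAccounting:
    def test_in_study_arithmetic(self):
        """A 1.3 Mb envelope with a 583 kb interior loss retains 0.7 Mb."""
        call = RegionCall("chrZ", 60_000_000, 61_300_000, "ZTR", 26,
                          interior_candidates=[(60_400_000, 60_983_000)])
        ds = wr.call_w_deletions(call)
        s = ds.summary()
        assert s["envelope_bp"] == 1_300_000
        assert s["deleted_bp"] == 583_000
        assert s["retained_bp"] == 717_000
        assert s["retained_mb"] == 0.7

    def test_no_interior_runs_retains_envelope(self):
        call = RegionCall("chrZ", 0, 500_000, "ZTR", 10)
        ds = wr.call_w_deletions(call)
        assert ds.retained_length == 500_000 and not ds.deletions

    def test_candidates_below_min_run_ignored(self):
        call = RegionCall("chrZ", 0, 500_000, "ZTR", 10,
                          interior_candidates=[(100_000, 150_000)])
        ds = wr.call_w_deletions(call, min_run=2, window_size=50_000)
        assert not ds.deletions

    def test_deletions_disjoint_and_sum_exact(self):
        call = RegionCall("chrZ", 0, 1_000_000, "ZTR", 20,
                          interior_candidates=[(100_000, 250_000),
                                               (500_000, 600_000)])
        ds = wr.call_w_deletions(call)
        ivs = sorted(ds.deletions)
        assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))
        assert ds.retained_length + ds.total_deleted == ds.envelope_length

    def test_non_ztr_call_rejected(self):
        with pytest.raises(ValueError):
            wr.call_w_deletions(RegionCall("c", 0, 100_000, "PAR", 2))


def random_variant_set(rng, seq, n=25):
    """Non-overlapping, left-normalized SNPs and 1-3 bp indels."""
    L = len(seq)
    pos = np.sort(rng.choice(np.arange(10, L - 10), n, replace=False))
    pos = pos[np.concatenate([[True], np.diff(pos) >= 12])]
    rows = []
    for p in pos:
        p = int(p)
        kind = rng.integers(3)
        if kind == 0:
            alt = [b for b in "ACGT" if b != seq[p]][rng.integers(3)]
            rows.append((p + 1, seq[p], alt))
        elif kind == 1:
            d = int(rng.integers(1, 4))
            rows.append((p + 1, seq[p:p + 1 + d], seq[p]))
        else:
            ins = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 4))))
            rows.append((p + 1, seq[p], seq[p] + ins))
    out = []
    for p, r, a in rows:
        p0, r2, a2 = wr.left_normalize(seq, p - 1, r, a)
        out.append((p0 + 1, r2, a2))
    return out


def test_variant_round_trip_exact():
    """Applying then re-deriving a variant set recovers it exactly."""
    rng = np.random.default_rng(12)
    for _ in range(15):
        seq = "".join(rng.choice(list("ACGT"), 2_000))
        rows = random_variant_set(rng, seq, n=20)
        w = wr.build_w_pseudosequence(seq, (0, len(seq)), vtable(rows))
        derived = wr.derive_variants(seq, w.sequence)
        got = set(zip(derived["pos"], derived["ref"], derived["alt"]))
        assert got == set(rows)
        signed = sum(len(a) - len(r) for _, r, a in rows)
        assert len(w.sequence) - len(seq) == signed
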
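import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scnakit.events import diploid_profile
from scnakit.metrics import (
    aberrant_fraction,
    compute_cell_metrics,
    deletion_amplification_fractions,
    detect_wgd,
    locus_status,
    modal_profile,
    subclonal_fraction,
)


def _flat(bins, a, b):
    cn = np.empty((bins.n_bins, 2), dtype=np.int64)
    cn[:, 0], cn[:, 1] = a, b
    return cn


class TestDetectWgd:
    def test_tetraploid_true(self, small_bins):
        assert detect_wgd(_flat(small_bins, 2, 2), small_bins)

    def test_diploid_false(self, small_bins):
        assert not detect_wgd(_flat(small_bins, 1, 1), small_bins)

    def test_doubled_profile_flagged(self, small_bins):
        """A profile that is exactly 2x a non-WGD profile with >=60% of the
        genome at (>=2,>=2) trips the rule."""
        base = _flat(small_bins, 1, 1)
        base[0:3, 1] = 0  # 30% LOH
        base[3, 0] = 2
        assert not detect_wgd(base, small_bins)
        assert detect_wgd(base * 2, small_bins)


class TestAberrantFraction:
    def test_all_diploid_zero(self, small_bins):
        assert aberrant_fraction(_flat(small_bins, 1, 1), small_bins, wgd=False) == 0.0

    def test_one_cnloh_bin_of_ten(self, small_bins):
        cn = _flat(small_bins, 1, 1)
        cn[4] = (2, 0)
        assert aberrant_fraction(cn, small_bins, wgd=False) == pytest.approx(0.1)

    def test_tetraploid_baseline_under_wgd(self, small_bins):
        assert aberrant_fraction(_flat(small_bins, 2, 2), small_bins, wgd=True) == 0.0

    def test_invariant_under_haplotype_swap(self, small_bins, rng):
        cn = rng.integers(0, 4, size=(10, 2))
        swapped = cn[:, ::-1]
        for wgd in (False, True):
            assert aberrant_fraction(cn, small_bins, wgd) == \
                aberrant_fraction(swapped, small_bins, wgd)


class TestDeletionAmplification:
    @pytest.mark.parametrize(
        "state, wgd, deleted, amplified",
        [
            ((2, 0), False, True, True),   # one allele below 1, one above 1
            ((2, 0), True, True, False),   # against the {2,2} baseline
            ((1, 1), False, False, False),
            ((1, 1), True, True, False),
            ((3, 2), True, False, True),
        ],
    )
    def test_single_bin_rules(self, small_bins, state, wgd, deleted, amplified):
        cn = _flat(small_bins, *state)
        d, a = deletion_amplification_fractions(cn, small_bins, wgd)
        assert (d == 1.0) is deleted
        assert (a == 1.0) is amplified

    def test_doubling_commutes_with_baseline_shift(self, small_bins, rng):
        """frac_deleted/amplified of 2x profile under {2,2} equal those of
        the base profile under {1,1}."""
        cn = rng.integers(0, 4, size=(10, 2))
        base = deletion_amplification_fractions(cn, small_bins, wgd=False)
        doubled = deletion_amplification_fractions(cn * 2, small_bins, wgd=True)
        assert base == doubled

    def test_aberrant_bounded_by_deleted_plus_amplified(self, small_bins, rng):
        for _ in range(20):
            cn = rng.integers(0, 5, size=(10, 2))
            for wgd in (False, True):
                ab = aberrant_fraction(cn, small_bins, wgd)
                d, a = deletion_amplification_fractions(cn, small_bins, wgd)
                assert ab <= d + a + 1e-12


class TestSubclonalFraction:
    def test_cell_equal_to_modal(self, small_bins):
        modal = _flat(small_bins, 1, 1)
        assert subclonal_fraction(modal, modal, small_bins) == 0.0

    def test_two_of_ten_bins_differ(self, small_bins):
        modal = _flat(small_bins, 1, 1)
        cn = modal.copy()
        cn[0] = (2, 1)
        cn[9] = (1, 0)
        assert subclonal_fraction(cn, modal, small_bins) == pytest.approx(0.2)

    def test_undoubled_subclone_inside_wgd_tumor(self, small_bins):
        """Cells that have not undergone the doubling differ from the modal
        (doubled) state exactly over the non-{1,1}-preserving region."""
        base = _flat(small_bins, 1, 1)
        base[0:4, 0] = 2  # aberrant region
        doubled = base * 2
        cells = [doubled] * 8 + [base] * 2
        modal = modal_profile(cells, small_bins)
        assert np.array_equal(modal, doubled)
        # every bin differs between base and doubled (1,1) vs (2,2) included
        assert subclonal_fraction(base, modal, small_bins) == pytest.approx(1.0)

    def test_modal_profile_majority(self, small_bins):
        a = _flat(small_bins, 1, 1)
        b = _flat(small_bins, 2, 1)
        modal = modal_profile([a, a, b], small_bins)
        assert np.array_equal(modal, a)


class TestLocusStatus:
    def test_loh(self, small_bins):
        cn = _flat(small_bins, 1, 0)
        st_ = locus_status(cn, small_bins, ("chr1", 2_500_000, 3_500_000), wgd=False)
        assert st_.status == "loh"
        assert st_.cn_at_locus == (1, 0)

    def test_cn_loh(self, small_bins):
        cn = _flat(small_bins, 2, 0)
        st_ = locus_status(cn, small_bins, ("chr1", 0, 1_000_000), wgd=False)
        assert st_.status == "cn_loh"

    def test_no_loh(self, small_bins):
        cn = _flat(small_bins, 1, 1)
        st_ = locus_status(cn, small_bins, ("chr1", 0, 500_000), wgd=False)
        assert st_.status == "no_loh"

    def test_wgd_baseline_shifts_cn_loh(self, small_bins):
        # {2,0} against a tetraploid expectation is plain LOH
        cn = _flat(small_bins, 2, 0)
        st_ = locus_status(cn, small_bins, ("chr1", 0, 1_000_000), wgd=True)
        assert st_.status == "loh"

    def test_majority_state_weighted_by_overlap(self, small_bins):
        cn = _flat(small_bins, 1, 1)
        cn[0] = (2, 0)
        # locus covers 0.9 of bin0 and 0.1 of bin1 -> majority (2,0)
        st_ = locus_status(cn, small_bins, ("chr1", 100_000, 1_100_000), wgd=False)
        assert st_.cn_at_locus == (2, 0)

    def test_locus_outside_genome_rejected(self, small_bins):
        with pytest.raises(ValueError):
            locus_status(_flat(small_bins, 1, 1), small_bins,
                         ("chrX", 0, 100), wgd=False)


def test_metrics_match_event_replay_on_truth(genome_bins):
    """Fractions computed on truth profiles equal fractions computed on
    profiles replayed from the edge events (exact)."""
    from scnakit.simulate import simulate_clonal_truth

    truth = simulate_clonal_truth(
        genome_bins, n_clones=3, n_truncal_events=12, n_private_events=4,
        p_wgd=1.0, deletion_bias=0.6, seed=17, min_event_bins=3)
    for cid in truth.clone_ids:
        direct = truth.clone_profiles[cid]
        replayed = truth.replay_profile(cid, genome_bins)
        wgd = truth.has_wgd(cid)
        assert aberrant_fraction(direct, genome_bins, wgd) == \
            aberrant_fraction(replayed, genome_bins, wgd)
        assert deletion_amplification_fractions(direct, genome_bins, wgd) == \
            deletion_amplification_fractions(replayed, genome_bins, wgd)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_cell_metrics_fractions_in_unit_interval(seed):
    import scnakit.genome as genome_mod

    bins = genome_mod.make_bins({"chr1": 7_000_000}, 2_000_000)
    rng = np.random.default_rng(seed)
    cn = rng.integers(0, 6, size=(bins.n_bins, 2))
    modal = diploid_profile(bins)
    m = compute_cell_metrics(cn, bins, modal, wgd=bool(rng.integers(2)), cell_id="c")
    for value in (m.frac_aberrant, m.frac_deleted, m.frac_amplified, m.frac_subclonal):
        assert 0.0 <= value <= 1.0
    assert m.frac_aberrant <= m.frac_deleted + m.frac_amplified + 1e-12
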
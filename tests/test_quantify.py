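"""Region quantification, percent-change contrasts, meta-domain profiles and
qPCR fold enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minidomain import (
    AnalysisConfig,
    Fragment,
    GenomeTable,
    QPCRTable,
    Region,
    coverage,
    meta_domain_profile,
    qpcr_fold_enrichment,
    quantify_regions,
)
from minidomain.domains import Domain
from minidomain.quantify import quant_table


def frags_at(midpoints, chrom="chr2L", length=80):
    return [
        Fragment(chrom, int(m) - length // 2, int(m) - length // 2 + length)
        for m in midpoints
    ]


REGION = Region("target", "chr2L", 4_000, 6_000)


class TestQuantifyRegions:
    def test_identical_samples_give_zero_percent_change(self):
        frags = frags_at(np.linspace(100, 9_900, 500))
        (q,) = quantify_regions(
            {"control": frags, "kd": list(frags)}, [REGION], "control"
        )
        assert q.percent_change["kd"] == pytest.approx(0.0)

    def test_percent_change_arithmetic(self):
        """Control 200 in-region of 1e4, knockdown 130 of 1e4: -35%."""
        rng = np.random.default_rng(0)
        out_mids = rng.integers(6_500, 9_500, size=9_800)
        control = frags_at(np.linspace(4_100, 5_900, 200)) + frags_at(out_mids)
        kd = frags_at(np.linspace(4_100, 5_900, 130)) + frags_at(
            rng.integers(6_500, 9_500, size=9_870)
        )
        (q,) = quantify_regions({"control": control, "kd": kd}, [REGION], "control")
        assert q.raw_counts == {"control": 200, "kd": 130}
        assert q.percent_change["kd"] == pytest.approx(-35.0)

    def test_region_with_no_fragments_is_flagged(self):
        frags = frags_at([8_000, 9_000])
        (q,) = quantify_regions({"control": frags, "kd": frags}, [REGION], "control")
        assert q.flagged and q.percent_change["kd"] is None

    def test_invariant_under_fragment_order_permutation(self):
        rng = np.random.default_rng(4)
        frags = frags_at(rng.integers(100, 9_900, size=400))
        shuffled = list(frags)
        rng.shuffle(shuffled)
        (a,) = quantify_regions({"control": frags, "kd": frags}, [REGION], "control")
        (b,) = quantify_regions(
            {"control": shuffled, "kd": shuffled}, [REGION], "control"
        )
        assert a.counts == b.counts

    def test_midpoint_counting_is_additive_across_adjacent_regions(self):
        rng = np.random.default_rng(8)
        frags = frags_at(rng.integers(100, 9_900, size=300))
        whole = Region("whole", "chr2L", 2_000, 8_000)
        left = Region("left", "chr2L", 2_000, 5_000)
        right = Region("right", "chr2L", 5_000, 8_000)
        qs = quantify_regions({"control": frags, "kd": frags},
                              [whole, left, right], "control")
        counts = {q.region.name: q.raw_counts["control"] for q in qs}
        assert counts["whole"] == counts["left"] + counts["right"]

    def test_missing_control_sample_rejected(self):
        with pytest.raises(ValueError, match="control"):
            quantify_regions({"kd": []}, [REGION], "control")

    def test_table_export_shape(self):
        frags = frags_at(np.linspace(100, 9_900, 50))
        qs = quantify_regions({"control": frags, "kd": frags}, [REGION], "control")
        table = quant_table(qs)
        assert set(table["sample"]) == {"control", "kd"}
        assert len(table) == 2


class TestMetaDomainProfile:
    GENOME = GenomeTable({"chr2L": 50_000})

    def test_uniform_domain_body_against_empty_flanks(self, cfg):
        frags = frags_at(np.arange(20_050, 29_950, 25), length=100)
        track = coverage(frags, self.GENOME, cfg.all_bin_bp)
        profile = meta_domain_profile(
            track, [Domain("chr2L", 20_000, 30_000, 1.0)], cfg
        )
        assert len(profile.values) == 100 + 2 * cfg.meta_flank_bp // 100
        body_mid = profile.body[10:90]
        assert body_mid.mean() == pytest.approx(4.0, rel=0.05)  # 100bp/25bp
        assert profile.five_prime_flank[:25].max() == 0.0
        assert profile.three_prime_flank[-25:].max() == 0.0

    def test_linearity_under_track_scaling(self, cfg):
        rng = np.random.default_rng(2)
        frags = frags_at(rng.integers(1_000, 49_000, size=2_000))
        track = coverage(frags, self.GENOME, cfg.all_bin_bp)
        domains = [Domain("chr2L", 10_000, 20_000, 1.0)]
        one = meta_domain_profile(track, domains, cfg)
        two = meta_domain_profile(track.scaled(2.0), domains, cfg)
        np.testing.assert_allclose(two.values, 2 * one.values)

    def test_narrow_domain_skipped_with_warning(self, cfg):
        track = coverage(frags_at([5_000]), self.GENOME, cfg.all_bin_bp)
        domains = [
            Domain("chr2L", 4_000, 4_050, 1.0),  # too narrow to rescale
            Domain("chr2L", 10_000, 20_000, 1.0),
        ]
        with pytest.warns(UserWarning, match="skipped"):
            profile = meta_domain_profile(track, domains, cfg)
        assert profile.n_domains == 1

    def test_no_domains_rejected(self, cfg):
        track = coverage([], self.GENOME, cfg.all_bin_bp)
        with pytest.raises(ValueError, match="domain"):
            meta_domain_profile(track, [], cfg)


class TestQPCR:
    def table(self, ct):
        return QPCRTable(ct, reference="Sas10")

    def test_all_equal_cts_give_unity(self):
        t = self.table({
            ("dhd", "cutrun"): 25.0, ("dhd", "mnase"): 25.0,
            ("Sas10", "cutrun"): 25.0, ("Sas10", "mnase"): 25.0,
        })
        assert qpcr_fold_enrichment(t, "dhd") == pytest.approx(1.0)

    def test_two_cycle_head_start_is_fourfold(self):
        """Ct_MNase(locus)=22 vs Ct_CutRun(locus)=20 with a neutral
        reference: 2**2 / 2**0 = 4."""
        t = self.table({
            ("dhd", "cutrun"): 20.0, ("dhd", "mnase"): 22.0,
            ("Sas10", "cutrun"): 25.0, ("Sas10", "mnase"): 25.0,
        })
        assert qpcr_fold_enrichment(t, "dhd") == pytest.approx(4.0)

    def test_reference_locus_scores_exactly_one(self):
        t = self.table({
            ("Sas10", "cutrun"): [24.2, 24.4], ("Sas10", "mnase"): [26.0, 26.2],
        })
        assert qpcr_fold_enrichment(t, "Sas10") == pytest.approx(1.0)

    def test_technical_duplicates_averaged_on_ct_scale(self):
        t = self.table({
            ("dhd", "cutrun"): [20.0, 22.0],  # mean Ct 21
            ("dhd", "mnase"): 23.0,
            ("Sas10", "cutrun"): 25.0, ("Sas10", "mnase"): 25.0,
        })
        assert qpcr_fold_enrichment(t, "dhd") == pytest.approx(4.0)

    @settings(derandomize=True, max_examples=30)
    @given(shift=st.floats(-5, 5))
    def test_invariant_under_constant_ct_shift(self, shift):
        base = {
            ("dhd", "cutrun"): 20.0, ("dhd", "mnase"): 23.5,
            ("Sas10", "cutrun"): 25.0, ("Sas10", "mnase"): 26.0,
        }
        shifted = {k: v + shift for k, v in base.items()}
        assert qpcr_fold_enrichment(self.table(shifted), "dhd") == pytest.approx(
            qpcr_fold_enrichment(self.table(base), "dhd")
        )

    def test_missing_cell_errors(self):
        t = self.table({("dhd", "cutrun"): 20.0, ("Sas10", "cutrun"): 25.0,
                        ("Sas10", "mnase"): 25.0})
        with pytest.raises(KeyError, match="mnase"):
            qpcr_fold_enrichment(t, "dhd")

    def test_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "qpcr.tsv"
        p.write_text(
            "locus\tassay\tct\n"
            "dhd\tcutrun\t20.0\ndhd\tcutrun\t20.2\ndhd\tmnase\t22.1\n"
            "Sas10\tcutrun\t25.0\nSas10\tmnase\t25.0\n"
        )
        t = QPCRTable.from_tsv(p)
        assert qpcr_fold_enrichment(t, "dhd") == pytest.approx(
            2 ** (22.1 - 20.1), rel=1e-6
        )
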
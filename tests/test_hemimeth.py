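"""Read qualification, per-read classes, region status, pattern matrices."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import imprintscreen as im
from imprintscreen import (
    HemiConfig,
    Region,
    SimConfig,
    classify_read,
    classify_region,
    hemimeth_screen,
    pattern_matrix,
    qualify_reads,
)
from conftest import make_read

REGION = Region("chr1", 0, 1000)


def reads_with_fractions(fracs, n_cpgs=10, start_at=0):
    """One read per requested mCpG fraction, n_cpgs calls each."""
    reads = []
    for i, f in enumerate(fracs):
        n_m = round(f * n_cpgs)
        states = ["M"] * n_m + ["U"] * (n_cpgs - n_m)
        reads.append(make_read(f"r{i}", range(start_at, start_at + n_cpgs), states))
    return reads


class TestQualify:
    def test_minimum_three_in_region_cpgs(self):
        reads = [
            make_read("r2", [10, 20], ["M", "M"]),
            make_read("r3", [10, 20, 30], ["M", "M", "U"]),
            make_read("r4", [10, 20, 30, 40], ["M"] * 4),
        ]
        kept = qualify_reads(reads, REGION)
        assert [r.read_id for r in kept] == ["r3", "r4"]

    def test_border_read_counts_inside_only(self):
        # 4 CpG calls but only 2 inside the region
        r = make_read("r", [990, 995, 1005, 1010], ["M"] * 4)
        assert qualify_reads([r], REGION) == []

    def test_empty_region_reads(self):
        r = make_read("r", [5000, 5010, 5020], ["M"] * 3)
        assert qualify_reads([r], REGION) == []


class TestClassifyRead:
    @pytest.mark.parametrize("n_meth,n_total,expected", [
        (1, 5, "hypo"),       # exactly 20%
        (4, 5, "hyper"),      # exactly 80%
        (5, 10, "intermediate"),
        (0, 3, "hypo"),
        (3, 3, "hyper"),
        (3, 10, "intermediate"),  # 30%
        (7, 10, "intermediate"),  # 70%
        (2, 10, "hypo"),
        (8, 10, "hyper"),
    ])
    def test_threshold_boundaries(self, n_meth, n_total, expected):
        r = make_read("r", range(n_total), ["M"] * n_meth + ["U"] * (n_total - n_meth))
        assert classify_read(r).klass == expected

    def test_region_restricted_fraction(self):
        # all-M inside the region, all-U outside
        r = make_read("r", [10, 20, 30, 2000, 2010], ["M", "M", "M", "U", "U"])
        c = classify_read(r, region=REGION)
        assert c.klass == "hyper" and c.n_cpgs == 3

    def test_no_calls_rejected(self):
        r = make_read("r", [], [], start=0, end=100)
        with pytest.raises(ValueError, match="no CpG calls"):
            classify_read(r)

    @given(st.integers(1, 30), st.data())
    def test_matches_brute_force_fraction(self, n, data):
        n_meth = data.draw(st.integers(0, n))
        r = make_read("r", range(n), ["M"] * n_meth + ["U"] * (n - n_meth))
        c = classify_read(r)
        frac = n_meth / n
        assert c.mcpg_fraction == pytest.approx(frac)
        expected = "hypo" if frac <= 0.2 else ("hyper" if frac >= 0.8 else "intermediate")
        assert c.klass == expected


class TestClassifyRegion:
    def test_hemi_pattern(self):
        reads = reads_with_fractions([0.0] * 40 + [1.0] * 40 + [0.5] * 20)
        call = classify_region(REGION, reads)
        assert call.status == "hemi_methylated"
        assert call.frac_hypo == pytest.approx(0.4)
        assert call.frac_hyper == pytest.approx(0.4)

    def test_all_hyper_is_hyper_dominant(self):
        call = classify_region(REGION, reads_with_fractions([1.0] * 100))
        assert call.status == "hyper_dominant"

    def test_background_is_hypo_dominant(self):
        call = classify_region(REGION, reads_with_fractions([0.0] * 90 + [0.5] * 10))
        assert call.status == "hypo_dominant"

    def test_thirty_reads_insufficient(self):
        call = classify_region(REGION, reads_with_fractions([1.0] * 30))
        assert call.status == "insufficient_support"
        assert call.n_qualified == 30

    def test_thirty_one_reads_sufficient(self):
        call = classify_region(REGION, reads_with_fractions([1.0] * 31))
        assert call.status == "hyper_dominant"

    def test_exactly_thirty_percent_is_hemi(self):
        reads = reads_with_fractions([0.0] * 30 + [1.0] * 30 + [0.5] * 40)
        assert classify_region(REGION, reads).status == "hemi_methylated"

    def test_mixed_not_hemi(self):
        reads = reads_with_fractions([0.0] * 20 + [1.0] * 50 + [0.5] * 30)
        assert classify_region(REGION, reads).status == "mixed_not_hemi"

    def test_read_order_invariance(self, rng):
        reads = reads_with_fractions(rng.uniform(0, 1, 80))
        call1 = classify_region(REGION, reads)
        call2 = classify_region(REGION, list(reversed(reads)))
        assert call1 == call2

    def test_adding_hyper_read_never_decreases_frac_hyper(self):
        reads = reads_with_fractions([0.0] * 40 + [1.0] * 40)
        before = classify_region(REGION, reads)
        extra = reads_with_fractions([1.0], start_at=0)
        extra = [make_read("extra", range(10), ["M"] * 10)]
        after = classify_region(REGION, reads + extra)
        assert after.frac_hyper >= before.frac_hyper


class TestPatternMatrix:
    def test_all_methylated_matrix(self):
        reads = [make_read(f"r{i}", [10, 20, 30, 40, 50], ["M"] * 5) for i in range(10)]
        mat = pattern_matrix(REGION, reads)
        assert mat.shape == (10, 5)
        assert (mat.to_numpy() == "M").all()

    def test_nine_reads_rejected(self):
        reads = [make_read(f"r{i}", [10, 20, 30], ["M"] * 3) for i in range(9)]
        with pytest.raises(ValueError, match="1 short"):
            pattern_matrix(REGION, reads)

    def test_gapped_read_ineligible(self):
        full = [make_read(f"r{i}", [10, 20, 30], ["M"] * 3) for i in range(10)]
        gapped = make_read("gap", [10, 30, 40], ["U"] * 3)  # skips CpG at 20
        mat = pattern_matrix(REGION, full + [gapped])
        assert "gap" not in mat.index
        assert 40 in mat.columns  # still part of the CpG universe

    def test_sort_deterministic(self, rng):
        fracs = rng.uniform(0, 1, 20)
        reads = reads_with_fractions(fracs)
        mat1 = pattern_matrix(REGION, reads)
        mat2 = pattern_matrix(REGION, list(reversed(reads)))
        assert list(mat1.index) == list(mat2.index)
        by_id = {r.read_id: r.mcpg_fraction for r in reads}
        row_fracs = [by_id[rid] for rid in mat1.index]
        assert row_fracs == sorted(row_fracs, reverse=True)


class TestScreenEndToEnd:
    def _reads_over_gdmr(self, mode, seed=0, depth=40):
        cfg = SimConfig(seed=seed, n_cpgs=60, cpg_spacing=20, read_length=150,
                        depth=depth, conversion_error=0.01, parental_mode=mode)
        pos, _, _ = im.simulate_locus(cfg)
        maps = (np.full(pos.size, 0.95), np.full(pos.size, 0.05))
        region = Region("chrSim", int(pos[0]), int(pos[-1]) + 1, "gdmr")
        reads = im.simulate_bisulfite_reads(maps, pos, cfg, mode)
        return region, reads

    def test_biparental_hemi_vs_bimaternal_hyper(self):
        region, cn_reads = self._reads_over_gdmr("biparental")
        _, pa_reads = self._reads_over_gdmr("bimaternal")
        table = hemimeth_screen([region], {"cn": cn_reads, "pa": pa_reads})
        status = dict(zip(table["sample_id"], table["status"]))
        assert status == {"cn": "hemi_methylated", "pa": "hyper_dominant"}

    def test_region_without_reads_insufficient(self):
        region, reads = self._reads_over_gdmr("biparental")
        far = Region("chrSim", 10_000_000, 10_001_000)
        table = hemimeth_screen([far], {"cn": reads})
        assert table["status"].tolist() == ["insufficient_support"]

    def test_sensitivity_over_seeded_replicates(self):
        """Planted biparental gDMRs are called hemi_methylated in >=95% of
        200 seeded simulations (error 0.05, depth 40, ~7 CpGs/read)."""
        hits = 0
        for seed in range(200):
            cfg = SimConfig(seed=seed, n_cpgs=40, cpg_spacing=20, read_length=150,
                            depth=40, conversion_error=0.05,
                            parental_mode="biparental")
            pos, _, _ = im.simulate_locus(cfg)
            maps = (np.ones(pos.size), np.zeros(pos.size))
            region = Region("chrSim", int(pos[0]), int(pos[-1]) + 1)
            reads = im.simulate_bisulfite_reads(maps, pos, cfg, "s")
            if classify_region(region, reads).status == "hemi_methylated":
                hits += 1
        assert hits >= 190


class TestHemiConfig:
    @pytest.mark.parametrize("kwargs", [
        {"hypo_max": 0.9, "hyper_min": 0.8}, {"hemi_class_frac": 0.6},
        {"min_cpgs_per_read": 0},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            HemiConfig(**kwargs)
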
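"""Filtering rules, rate computation, bins and trinucleotide spectra."""

import math

import numpy as np
import pandas as pd
import pytest

from bgerr.datamodel import ALL_CLASSES, BASES, SubstitutionClass
from bgerr.profiling import (
    FilterConfig,
    apply_pairwise_variant_exclusion,
    build_site_counts,
    compute_error_profile,
    error_free_fraction,
    fragment_bin_profile,
    observations_to_frame,
    position_error_table,
    refit_signatures,
    spectrum_channels,
    trinuc_spectrum,
)


def _site_df(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "A", "C", "G", "T"])
    df["depth"] = df[list(BASES)].sum(axis=1)
    return df


class TestFilterConfig:
    def test_defaults_are_q30_500x_one_percent(self):
        f = FilterConfig()
        assert f.min_base_quality == 30
        assert f.min_depth == 500
        assert f.germline_af_threshold == 0.01

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            FilterConfig(min_depth=0)
        with pytest.raises(ValueError):
            FilterConfig(germline_af_threshold=1.5)


class TestBuildSiteCounts:
    def test_quality_threshold(self, make_obs):
        observations = [make_obs(qual=37 if i < 8 else 29, base="C")
                        for i in range(10)]
        df = build_site_counts(observations, FilterConfig())
        assert df["depth"].iloc[0] == 8

    def test_matches_naive_tally_oracle(self, make_obs):
        """Random observations tally identically to a nested-loop count."""
        rng = np.random.default_rng(3)
        observations = [
            make_obs(pos=int(rng.integers(20)),
                     ref="ACGT"[rng.integers(4) % 4],
                     base="ACGT"[rng.integers(4)],
                     qual=int(rng.choice([25, 31, 37])))
            for _ in range(500)
        ]
        # pin one ref base per position (as a real reference would)
        ref_at = {}
        fixed = []
        for o in observations:
            ref_at.setdefault(o.pos, o.ref_base)
            fixed.append(o._replace(ref_base=ref_at[o.pos]))
        filt = FilterConfig(min_base_quality=30)
        df = build_site_counts(fixed, filt).set_index("pos")
        oracle: dict[int, dict[str, int]] = {}
        for o in fixed:
            if o.base_quality < 30:
                continue
            oracle.setdefault(o.pos, {b: 0 for b in BASES})
            oracle[o.pos][o.obs_base] += 1
        assert set(df.index) == set(oracle)
        for pos, counts in oracle.items():
            for b in BASES:
                assert df.loc[pos, b] == counts[b]
            assert df.loc[pos, "ref"] == ref_at[pos]

    def test_attrition_accounts_for_every_base(self, make_obs):
        observations = [make_obs(qual=q) for q in [37, 29, 31, 10, 40]]
        att = {}
        build_site_counts(observations, FilterConfig(), attrition=att)
        assert att["bases_in"] == att["bases_retained"] + att["removed_low_quality"]
        assert att["removed_low_quality"] == 2

    def test_empty_input(self):
        df = build_site_counts([], FilterConfig())
        assert len(df) == 0


class TestBlacklistAndOverlap:
    def test_tsv_blacklist(self, tmp_path):
        from bgerr.profiling import load_variant_blacklist

        p = tmp_path / "bl.tsv"
        p.write_text("# chrom pos alt\nchr1\t100\tT\nchr2\t5\tA\n")
        assert load_variant_blacklist(p) == frozenset(
            {("chr1", 100, "T"), ("chr2", 5, "A")})

    def test_vcf_blacklist_converts_coordinates(self, tmp_path):
        from bgerr.profiling import load_variant_blacklist

        p = tmp_path / "bl.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t101\t.\tC\tT\t.\t.\t.\n"
            "chr1\t200\t.\tG\tA,C\t.\t.\t.\n")
        # VCF POS is 1-based; internal coordinates are 0-based
        assert load_variant_blacklist(p) == frozenset(
            {("chr1", 100, "T"), ("chr1", 199, "A"), ("chr1", 199, "C")})

    def test_malformed_tsv_rejected(self, tmp_path):
        from bgerr.profiling import load_variant_blacklist

        p = tmp_path / "bad.tsv"
        p.write_text("chr1\t100\n")
        with pytest.raises(ValueError, match="3 columns"):
            load_variant_blacklist(p)

    def test_dedup_mate_overlap_keeps_best_single_count(self, make_obs):
        from bgerr.profiling import dedup_mate_overlap

        frame = observations_to_frame([
            make_obs(pos=10, qual=30, read_id="p1/1"),
            make_obs(pos=10, qual=38, read_id="p1/2"),  # overlap: same pair
            make_obs(pos=10, qual=35, read_id="p2/1"),
            make_obs(pos=11, qual=30, read_id="p1/1"),
        ])
        out = dedup_mate_overlap(frame)
        assert len(out) == 3
        kept = out[(out["pos"] == 10) & (out["pair_id"] == "p1")]
        assert kept["qual"].iloc[0] == 38


class TestPairwiseVariantExclusion:
    def test_high_af_in_one_member_masks_both(self):
        cf = _site_df([("c", 1, "A", 995, 0, 5, 0)])
        gd = _site_df([("c", 1, "A", 700, 0, 300, 0)])  # 30% G in gDNA only
        mask = apply_pairwise_variant_exclusion(cf, gd, FilterConfig())
        assert mask == frozenset({("c", 1, "G")})

    def test_below_threshold_retained(self):
        cf = _site_df([("c", 1, "A", 991, 0, 9, 0)])  # 0.9%
        gd = _site_df([("c", 1, "A", 991, 0, 9, 0)])
        assert apply_pairwise_variant_exclusion(cf, gd, FilterConfig()) == frozenset()

    def test_blacklist_always_included(self):
        cf = _site_df([("c", 1, "A", 1000, 0, 0, 0)])
        filt = FilterConfig(variant_blacklist=frozenset({("c", 5, "T")}))
        mask = apply_pairwise_variant_exclusion(cf, cf, filt)
        assert ("c", 5, "T") in mask

    def test_planted_germline_variants_exactly_masked(self, small_counts_dataset):
        """The masked set equals the simulator's planted-variant ledger."""
        ds = small_counts_dataset
        filt = FilterConfig()
        for pair_id, (cf_id, g_id) in ds.pairs().items():
            mask = apply_pairwise_variant_exclusion(
                ds.counts[cf_id], ds.counts[g_id], filt)
            assert mask == ds.ledger.germline_alleles(pair_id)


class TestComputeErrorProfile:
    def test_single_site_rate(self):
        counts = _site_df([("c", 1, "C", 0, 999, 0, 1)])
        p = compute_error_profile(counts, FilterConfig(), "s")
        assert p.rates[SubstitutionClass("C", "T")] == pytest.approx(1e-3)
        assert p.eligible_bases["C"] == 1000

    def test_all_reference_zero_rates(self):
        counts = _site_df([("c", i, "A", 1000, 0, 0, 0) for i in range(5)])
        p = compute_error_profile(counts, FilterConfig(), "s")
        assert all(r == 0 for r in p.rates.values() if r == r)
        assert p.total_rate == 0

    def test_shallow_site_excluded(self):
        counts = _site_df([("c", 1, "C", 0, 499, 0, 0),
                           ("c", 2, "C", 0, 600, 0, 0)])
        p = compute_error_profile(counts, FilterConfig(), "s")
        assert p.n_eligible_positions == 1
        assert p.eligible_bases["C"] == 600

    def test_pair_depth_eligibility_is_joint(self):
        counts = _site_df([("c", 1, "C", 0, 800, 0, 0),
                           ("c", 2, "C", 0, 800, 0, 0)])
        pair = _site_df([("c", 1, "C", 0, 450, 0, 0),
                         ("c", 2, "C", 0, 900, 0, 0)])
        p = compute_error_profile(counts, FilterConfig(), "s", pair_depths=[pair])
        assert p.n_eligible_positions == 1

    def test_masked_allele_leaves_denominator(self):
        counts = _site_df([("c", 1, "C", 300, 690, 0, 10)])
        mask = frozenset({("c", 1, "A")})  # germline A allele
        p = compute_error_profile(counts, FilterConfig(), "s", mask=mask)
        assert p.error_counts[SubstitutionClass("C", "A")] == 0
        assert p.error_counts[SubstitutionClass("C", "T")] == 10
        assert p.eligible_bases["C"] == 1000  # masked depth still counts

    def test_conservation_of_counts(self, small_counts_dataset):
        """Errors + reference bases + masked alleles = all eligible bases."""
        ds = small_counts_dataset
        filt = FilterConfig()
        cf_id, g_id = ds.pairs()["P1"]
        mask = apply_pairwise_variant_exclusion(ds.counts[cf_id], ds.counts[g_id], filt)
        counts = ds.counts[cf_id]
        p = compute_error_profile(counts, filt, cf_id, mask=mask,
                                  pair_depths=[ds.counts[g_id]])
        elig = counts[counts["depth"] >= filt.min_depth]
        allele = elig[list(BASES)].to_numpy()
        ref_idx = np.searchsorted(np.array(BASES), elig["ref"].to_numpy())
        ref_depth = int(allele[np.arange(len(elig)), ref_idx].sum())
        masked_depth = 0
        lookup = elig.set_index("pos")
        for chrom, pos, alt in mask:
            if pos in lookup.index and lookup.loc[pos, "ref"] != alt:
                masked_depth += int(lookup.loc[pos, alt])
        total_errors = sum(p.error_counts.values())
        assert total_errors + ref_depth + masked_depth == int(elig["depth"].sum())

    def test_exclude_positions(self):
        counts = _site_df([("c", 1, "C", 0, 999, 0, 1),
                           ("c", 2, "C", 0, 1000, 0, 0)])
        p = compute_error_profile(counts, FilterConfig(), "s",
                                  exclude_positions={("c", 1)})
        assert p.error_counts[SubstitutionClass("C", "T")] == 0
        assert p.n_eligible_positions == 1


class TestErrorFreeFraction:
    def test_all_reference_is_100(self):
        counts = _site_df([("c", i, "A", 1000, 0, 0, 0) for i in range(4)])
        assert error_free_fraction(counts, FilterConfig()) == 100.0

    def test_one_errored_site_of_four(self):
        rows = [("c", i, "A", 1000, 0, 0, 0) for i in range(3)]
        rows.append(("c", 3, "A", 999, 1, 0, 0))
        assert error_free_fraction(_site_df(rows), FilterConfig()) == 75.0

    def test_no_eligible_positions_is_nan(self):
        counts = _site_df([("c", 1, "A", 100, 0, 0, 0)])
        assert math.isnan(error_free_fraction(counts, FilterConfig()))

    def test_masked_errors_do_not_count(self):
        counts = _site_df([("c", 1, "A", 900, 0, 100, 0)])
        frac = error_free_fraction(counts, FilterConfig(),
                                   mask=frozenset({("c", 1, "G")}))
        assert frac == 100.0

    def test_matches_binomial_thinning_expectation(self):
        """Observed fraction within 3 SE of the closed-form expectation."""
        from bgerr.synthetic import gdna_counts_preset, simulate_counts

        cfg = gdna_counts_preset(panel_bp=3000, n_samples=1,
                                 germline_het_sites=0)
        ds = simulate_counts(cfg, None, seed=21)
        counts = ds.counts["cf1"] if "cf1" in ds.counts else ds.counts["g1"]
        frac = error_free_fraction(counts, FilterConfig())
        # per site: P(error-free) = (1 - 3 * class rate)^depth
        p_err = 3 * 0.9e-5
        expect = 100.0 * (1 - p_err) ** cfg.depth
        se = 100.0 * math.sqrt(
            (expect / 100) * (1 - expect / 100) / cfg.panel_bp)
        assert abs(frac - expect) < 3 * se


class TestPositionErrorTable:
    def test_single_sample_single_site(self):
        counts = _site_df([("c", 1, "C", 0, 990, 0, 10)])
        table = position_error_table({"s1": counts}, FilterConfig())
        ct = table[(table["class"] == "C>T")]
        assert ct["rate"].iloc[0] == pytest.approx(0.01)
        total = table[table["class"] == "total"]
        assert total["rate"].iloc[0] == pytest.approx(0.01)

    def test_site_shallow_in_any_sample_absent_for_all(self):
        a = _site_df([("c", 1, "C", 0, 1000, 0, 0), ("c", 2, "C", 0, 1000, 0, 0)])
        b = _site_df([("c", 1, "C", 0, 499, 0, 0), ("c", 2, "C", 0, 800, 0, 0)])
        table = position_error_table({"a": a, "b": b}, FilterConfig())
        assert set(table["pos"]) == {2}

    def test_masked_allele_rows_absent(self):
        counts = _site_df([("c", 1, "C", 100, 890, 0, 10)])
        table = position_error_table({"s": counts}, FilterConfig(),
                                     mask=frozenset({("c", 1, "A")}))
        assert "C>A" not in set(table["class"])
        total = table[table["class"] == "total"]["rate"].iloc[0]
        assert total == pytest.approx(10 / 1000)

    def test_row_totals_reconcile_with_profile(self, small_counts_dataset):
        """Summed per-position errors equal the profile's error counts."""
        ds = small_counts_dataset
        counts = ds.counts["g1"]
        filt = FilterConfig()
        table = position_error_table({"g1": counts}, filt)
        p = compute_error_profile(counts, filt, "g1")
        depth = counts.set_index("pos")["depth"]
        for c in ALL_CLASSES:
            rows = table[table["class"] == str(c)]
            recon = (rows["rate"].to_numpy()
                     * depth.reindex(rows["pos"]).to_numpy()).sum()
            assert round(recon) == p.error_counts[c]


class TestFragmentBinProfile:
    def _frame(self, rows):
        return observations_to_frame(rows)

    def test_end_planted_errors_land_in_bin_1(self, make_obs):
        rows = [make_obs(pos=i, ref="C", base="A", dist=d)
                for i, d in enumerate([1, 2, 3, 4, 5])]
        rows += [make_obs(pos=i + 10, ref="C", base="C", dist=20)
                 for i in range(5)]
        bp = fragment_bin_profile(self._frame(rows), FilterConfig(), "s")
        assert bp.bin_counts.loc[1, "C>A"] == 5
        assert bp.bin_counts.drop(index=1).to_numpy().sum() == 0

    def test_beyond_50bp_not_binned(self, make_obs):
        rows = [make_obs(dist=51, base="T", ref="C")]
        bp = fragment_bin_profile(self._frame(rows), FilterConfig(), "s")
        assert bp.bin_counts.to_numpy().sum() == 0
        assert bp.bin_eligible_bases.to_numpy().sum() == 0

    def test_quality_filter_applies(self, make_obs):
        rows = [make_obs(dist=1, base="A", ref="C", qual=29)]
        bp = fragment_bin_profile(self._frame(rows), FilterConfig(), "s")
        assert bp.bin_eligible_bases.to_numpy().sum() == 0

    def test_mask_removes_numerator_not_denominator(self, make_obs):
        rows = [make_obs(pos=7, ref="C", base="A", dist=3)]
        bp = fragment_bin_profile(self._frame(rows), FilterConfig(), "s",
                                  mask=frozenset({("chr1", 7, "A")}))
        assert bp.bin_counts.loc[1, "C>A"] == 0
        assert bp.bin_eligible_bases.loc[1, "C"] == 1

    def test_eligible_position_restriction(self, make_obs):
        rows = [make_obs(pos=7, dist=3), make_obs(pos=8, dist=3)]
        bp = fragment_bin_profile(self._frame(rows), FilterConfig(), "s",
                                  eligible_positions=[("chr1", 7)])
        assert bp.bin_eligible_bases.loc[1, "C"] == 1

    def test_uniform_rate_gives_flat_bins(self):
        """With no end effect, the 10 bin rates are statistically level."""
        from bgerr.synthetic import cfdna_reads_preset, simulate_reads

        cfg = cfdna_reads_preset(n_fragments=20_000, n_samples=1,
                                 seq_error_rate=0.0)
        ds = simulate_reads(cfg, None, seed=31, lean_frames=True)
        bp = fragment_bin_profile(ds.observations["cf1"], FilterConfig(), "cf1")
        totals = bp.total_bin_rates()
        counts = bp.bin_counts.sum(axis=1).to_numpy(dtype=float)
        # molecule-level errors arrive in clusters of mean family size 2.79
        se = np.sqrt(counts * 2.79) / bp.bin_eligible_bases.sum(axis=1).to_numpy()
        grand = totals.mean()
        assert (np.abs(totals - grand) < 4 * (se + 1e-12)).all()

    def test_end_effect_ratio_near_multiplier(self):
        """A 5x first-5-bp multiplier yields a ~5x bin-1/rest rate ratio."""
        from bgerr.synthetic import gdna_reads_preset, simulate_reads

        cfg = gdna_reads_preset(n_fragments=30_000, n_samples=1,
                                seq_error_rate=0.0)
        ds = simulate_reads(None, cfg, seed=32, lean_frames=True)
        bp = fragment_bin_profile(ds.observations["g1"], FilterConfig(), "g1")
        collapsed = bp.collapsed_bin_rates()["C:G>A:T"]
        ratio = collapsed.loc[1] / collapsed.loc[2:].mean()
        n1 = bp.bin_counts.loc[1, ["C>A", "G>T"]].sum() / 2.79
        n2 = bp.bin_counts.loc[2:, ["C>A", "G>T"]].to_numpy().sum() / 2.79
        tol = 3 * math.sqrt(1 / n1 + 1 / n2)  # 3 SE on the log ratio
        assert abs(math.log(ratio / 5.0)) < tol


class TestMonotonicity:
    def test_raising_thresholds_never_gains_eligible_bases(self):
        from bgerr.synthetic import cfdna_reads_preset, simulate_reads

        cfg = cfdna_reads_preset(
            n_fragments=6000, n_samples=1,
            quality_distribution=((25, 0.2), (33, 0.4), (40, 0.4)))
        ds = simulate_reads(cfg, None, seed=33, lean_frames=True)
        frame = ds.observations["cf1"]
        base = compute_error_profile(
            build_site_counts(frame, FilterConfig(min_base_quality=30)),
            FilterConfig(min_depth=500), "s")
        stricter_q = compute_error_profile(
            build_site_counts(frame, FilterConfig(min_base_quality=40)),
            FilterConfig(min_depth=500), "s")
        stricter_d = compute_error_profile(
            build_site_counts(frame, FilterConfig(min_base_quality=30)),
            FilterConfig(min_depth=1000), "s")
        for b in BASES:
            assert stricter_q.eligible_bases[b] <= base.eligible_bases[b]
            assert stricter_d.eligible_bases[b] <= base.eligible_bases[b]


class TestLocality:
    def test_excluding_positions_is_additive(self, small_counts_dataset):
        """Re-profiling after exclusion only subtracts the excluded sites."""
        counts = small_counts_dataset.counts["cf1"]
        filt = FilterConfig()
        excl = {("panel1", int(p)) for p in counts["pos"].iloc[100:200]}
        full = compute_error_profile(counts, filt, "s")
        remaining = compute_error_profile(counts, filt, "s",
                                          exclude_positions=excl)
        removed_only = counts[counts["pos"].isin([p for _, p in excl])]
        removed = compute_error_profile(removed_only, filt, "s")
        for c in ALL_CLASSES:
            assert (remaining.error_counts[c] + removed.error_counts[c]
                    == full.error_counts[c])
        for b in BASES:
            assert (remaining.eligible_bases[b] + removed.eligible_bases[b]
                    == full.eligible_bases[b])


class TestTrinucSpectrum:
    def test_single_error_in_context(self):
        ref = {"c": "AACAT"}
        spec = trinuc_spectrum([("c", 2, "C", "T")], ref)
        assert spec.counts["A[C>T]A"] == 1
        assert spec.counts.sum() == 1

    def test_purine_reference_maps_to_complement_strand(self):
        # G>A at pos 2 of T G G: complement-strand context is C[C>T]A
        ref = {"c": "ATGGA"}
        spec = trinuc_spectrum([("c", 2, "G", "A")], ref)
        assert spec.counts["C[C>T]A"] == 1

    def test_contig_edges_dropped_and_counted(self):
        ref = {"c": "CAT"}
        spec = trinuc_spectrum([("c", 0, "C", "T"), ("c", 2, "T", "G"),
                                ("c", 1, "A", "G")], ref)
        assert spec.n_dropped_edge == 2
        assert spec.counts.sum() == 1

    def test_fraction_normalization(self):
        ref = {"c": "AACATTCAA"}
        spec = trinuc_spectrum([("c", 2, "C", "T"), ("c", 7, "C", "G")], ref)
        assert spec.fractions.sum() == pytest.approx(1.0)

    def test_identity_refit(self):
        rng = np.random.default_rng(5)
        channels = spectrum_channels()
        sig = rng.dirichlet(np.ones(96))
        sigs = pd.DataFrame({"S1": sig, "S2": rng.dirichlet(np.ones(96))},
                            index=channels)
        from bgerr.profiling import TrinucSpectrum

        counts = pd.Series((sig * 100_000).round().astype(int), index=channels)
        weights = refit_signatures(TrinucSpectrum(counts), sigs)
        assert weights["S1"] > 0.99

    def test_mixture_recovery_within_5_percent(self):
        """A 0.7/0.3 signature mixture at 1e4 draws refits within 0.05."""
        rng = np.random.default_rng(6)
        channels = spectrum_channels()
        a = np.zeros(96); a[:48] = rng.dirichlet(np.ones(48))
        b = np.zeros(96); b[48:] = rng.dirichlet(np.ones(48))
        sigs = pd.DataFrame({"A": a, "B": b}, index=channels)
        mixture = 0.7 * a + 0.3 * b
        draws = rng.multinomial(10_000, mixture)
        from bgerr.profiling import TrinucSpectrum

        weights = refit_signatures(
            TrinucSpectrum(pd.Series(draws, index=channels)), sigs)
        assert abs(weights["A"] - 0.7) < 0.05
        assert abs(weights["B"] - 0.3) < 0.05

    def test_malformed_matrix_rejected(self):
        from bgerr.profiling import TrinucSpectrum

        channels = spectrum_channels()
        bad = pd.DataFrame({"S": np.full(96, 0.5)}, index=channels)
        spec = TrinucSpectrum(pd.Series(1, index=channels))
        with pytest.raises(ValueError, match="sum to 1"):
            refit_signatures(spec, bad)
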
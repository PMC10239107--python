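"""Somatic filtering, the VAF-window LOH rule, MSI cutoffs and enrichment."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from epitriage.io import Region
from epitriage.somatic import (
    LOHCall,
    enrichment,
    filter_somatic,
    fisher_2x2,
    germline_het,
    loh_site,
    msi_call,
    mutation_matrix,
    region_loh,
    second_hit,
)


def rec(**kw):
    base = dict(
        sample_id="s1", chrom="3", pos=37_050_000, ref="A", alt="G", gene="MLH1",
        filter_status="PASS", vaf_tumour=0.4, vaf_germline=0.0, depth_tumour=100,
        consequence="missense", origin="somatic",
    )
    base.update(kw)
    return base


class TestFilterSomatic:
    @pytest.mark.parametrize(
        "kw,kept",
        [
            (dict(vaf_tumour=0.05, depth_tumour=100), True),
            (dict(vaf_tumour=0.04, depth_tumour=30), True),  # inclusive minima
            (dict(vaf_tumour=0.03), False),
            (dict(filter_status="LowEVS", vaf_tumour=0.5, depth_tumour=200), False),
            (dict(depth_tumour=29), False),
        ],
    )
    def test_rules(self, kw, kept):
        out = filter_somatic(pd.DataFrame([rec(**kw)]))
        assert (len(out) == 1) == kept

    def test_idempotent_and_order_invariant(self):
        df = pd.DataFrame([rec(pos=p, vaf_tumour=v) for p, v in
                           [(1, 0.5), (2, 0.01), (3, 0.2), (4, 0.045)]])
        once = filter_somatic(df)
        assert filter_somatic(once).equals(once)
        rev = filter_somatic(df.iloc[::-1])
        assert set(rev["pos"]) == set(once["pos"])


class TestSiteRules:
    @pytest.mark.parametrize("vaf,het", [(0.5, True), (0.29, False), (0.30, True),
                                         (0.70, True), (0.71, False)])
    def test_germline_het_inclusive_window(self, vaf, het):
        assert germline_het(vaf) is het

    @pytest.mark.parametrize(
        "vg,vt,expect",
        [
            (0.5, 0.95, True),   # toward homozygous-alternative
            (0.5, 0.6, False),   # shift below 0.3
            (0.45, 0.10, True),  # toward homozygous-reference
            (0.5, 0.8, False),   # exactly 0.3 is not enough (strict)
        ],
    )
    def test_loh_site_examples(self, vg, vt, expect):
        assert loh_site(vg, vt) is expect

    def test_non_het_site_is_an_error(self):
        with pytest.raises(ValueError, match="heterozygous"):
            loh_site(0.1, 0.9)

    def test_grid_oracle_agreement(self):
        """Exhaustive agreement with a literal re-statement of the printed rule
        on the full 0.01-resolution VAF grid."""
        # exact decimal arithmetic in centi-units avoids float noise at the
        # 0.3 boundary (the rule is stated on two-decimal VAFs)
        for vg_c in range(30, 71):
            for vt_c in range(0, 101):
                literal = abs(vt_c - vg_c) > 30
                assert loh_site(vg_c / 100, vt_c / 100) == literal, (vg_c, vt_c)

    def test_magnitude_only_mode(self):
        # with direction off the call reduces to the pure |delta| > 0.3 rule
        assert loh_site(0.5, 0.85, require_direction=False)
        assert loh_site(0.5, 0.85, require_direction=True)


WINDOW = Region(name="MLH1", chrom="3", start=37_000_000, end=37_100_000)


def het_sites(vafs_t, vaf_g=0.5, sample="s1"):
    return pd.DataFrame(
        [rec(sample_id=sample, pos=37_010_000 + 1000 * i, vaf_germline=vaf_g,
             vaf_tumour=vt, origin="germline", consequence="intron")
         for i, vt in enumerate(vafs_t)]
    )


class TestRegionLoh:
    def test_all_sites_supporting(self):
        call = region_loh(het_sites([0.95, 0.9, 0.05, 0.92]), WINDOW)
        assert call.loh and call.n_informative == 4 and call.n_supporting == 4

    def test_zero_informative_sites(self):
        df = het_sites([0.5])
        df["vaf_germline"] = 0.05  # homozygous germline: not informative
        call = region_loh(df, WINDOW)
        assert not call.loh and call.n_informative == 0

    def test_below_min_fraction(self):
        call = region_loh(het_sites([0.95, 0.5, 0.5, 0.5]), WINDOW)
        assert not call.loh and call.n_supporting == 1

    def test_direction_summary(self):
        call = region_loh(het_sites([0.95, 0.05]), WINDOW)
        assert call.direction_summary == {"to_hom_ref": 1, "to_hom_alt": 1}


class TestSecondHit:
    def _loh(self, flag):
        return LOHCall("s1", "MLH1", 4, 4 if flag else 0, flag, {})

    def test_snv_only(self):
        snv = pd.DataFrame([rec(consequence="p.S131Ter (stop_gained)")])
        assert second_hit(snv, self._loh(False)) == "somatic_variant"

    def test_loh_only(self):
        assert second_hit(pd.DataFrame(columns=["gene", "consequence"]), self._loh(True)) == "LOH"

    def test_both_and_none(self):
        snv = pd.DataFrame([rec(consequence="splice_acceptor")])
        assert second_hit(snv, self._loh(True)) == "both"
        assert second_hit(snv.iloc[:0], self._loh(False)) == "none"

    def test_benign_consequence_not_a_hit(self):
        syn = pd.DataFrame([rec(consequence="synonymous")])
        assert second_hit(syn, self._loh(False)) == "none"


class TestMsi:
    @pytest.mark.parametrize(
        "score,platform,expect",
        [(0.245, "WES", "MSI-H"), (0.244, "WES", "MSS"),
         (0.250, "panel", "MSS"), (0.252, "panel", "MSI-H"), (0.30, "panel", "MSI-H")],
    )
    def test_cutoffs_inclusive(self, score, platform, expect):
        assert msi_call(score, platform) == expect

    def test_unknown_platform(self):
        with pytest.raises(ValueError, match="platform"):
            msi_call(0.3, "WGS")


def hypergeom_two_sided(a, b, c, d):
    """Independent oracle: two-sided Fisher P by hypergeometric enumeration."""
    n, K, N = a + b + c + d, a + b, a + c
    lo, hi = max(0, K + N - n), min(K, N)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, K, N)
    return float(pmf[pmf <= pmf[support == a] * (1 + 1e-9)].sum())


class TestEnrichment:
    def test_extreme_table_exact_p(self):
        p, _ = fisher_2x2(5, 0, 0, 5)
        assert p == pytest.approx(2 / 252, rel=1e-12)  # 1/126

    def test_oracle_agreement_sampled_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 11, size=4)
            if a + b + c + d == 0:
                continue
            p, _ = fisher_2x2(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(hypergeom_two_sided(a, b, c, d), abs=1e-12)

    def test_gene_mutated_everywhere_uninformative(self):
        mat = pd.DataFrame([[1, 1, 1, 1]], index=["APC"], columns=list("abcd"))
        labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
        out = enrichment(mat, labels, 1)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_counts_partition_cohort(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.integers(0, 2, (4, 12)), index=list("WXYZ"),
                           columns=[f"s{i}" for i in range(12)])
        labels = pd.Series([1] * 5 + [2] * 7, index=mat.columns)
        out = enrichment(mat, labels, 1)
        assert (out[["a", "b", "c", "d"]].sum(axis=1) == 12).all()

    def test_permutation_calibration(self):
        """Under label permutation ~5% of genes reach P < 0.05."""
        rng = np.random.default_rng(7)
        n_genes, n_samples = 60, 30
        mat = pd.DataFrame(rng.integers(0, 2, (n_genes, n_samples)),
                           index=[f"g{i}" for i in range(n_genes)],
                           columns=[f"s{i}" for i in range(n_samples)])
        hits = total = 0
        for _ in range(25):
            labels = pd.Series(rng.permutation([1] * 10 + [2] * 20), index=mat.columns)
            out = enrichment(mat, labels, 1)
            hits += (out["p_value"] < 0.05).sum()
            total += len(out)
        # Fisher is conservative at these margins; the false-positive rate
        # must stay at or below nominal
        assert hits / total < 0.06

    def test_single_cluster_rejected(self):
        mat = pd.DataFrame([[1, 0]], index=["APC"], columns=list("ab"))
        with pytest.raises(ValueError, match="2 clusters"):
            enrichment(mat, pd.Series([1, 1], index=list("ab")), 1)


class TestMutationMatrix:
    def test_tmb_conserves_retained_records(self):
        df = pd.DataFrame([
            rec(sample_id="s1", gene="APC", pos=1),
            rec(sample_id="s1", gene="APC", pos=2),
            rec(sample_id="s1", gene="KRAS", pos=3),
            rec(sample_id="s2", gene="APC", pos=4, vaf_tumour=0.01),  # filtered out
        ])
        mat, tmb = mutation_matrix(df)
        assert tmb["s1"] == 3 and tmb["s2"] == 0
        assert mat.loc["APC", "s1"] == 1 and mat.loc["APC", "s2"] == 0
        assert (tmb >= mat.sum(axis=0)).all()
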
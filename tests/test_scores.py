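"""Region-level methylation scoring rules."""
import numpy as np
import pandas as pd
import pytest

from epitriage import registry
from epitriage.io import BetaMatrix, Region
from epitriage.scores import (
    cimp_call,
    mlh1_c_region_score,
    region_mean,
    select_variable_probes,
)

C_PROBES = registry.mlh1_c_region_probes()


def beta_with_c_region(c_betas, sample="s"):
    return BetaMatrix(values=pd.DataFrame({sample: list(c_betas)}, index=C_PROBES))


class TestMlh1CRegion:
    def test_threshold_is_strict(self):
        score = mlh1_c_region_score(beta_with_c_region([0.2] * 4), "s")
        assert score.mean_beta == pytest.approx(0.2)
        assert score.status == "negative"

    def test_hand_computed_mean_positive(self):
        score = mlh1_c_region_score(beta_with_c_region([0.9, 0.8, 0.7, 0.68]), "s")
        assert score.mean_beta == pytest.approx(0.77, abs=1e-12)
        assert score.status == "positive"

    def test_weak_promoter_methylation_stays_negative(self):
        score = mlh1_c_region_score(beta_with_c_region([0.14] * 4), "s")
        assert score.mean_beta == pytest.approx(0.14)
        assert score.status == "negative"

    def test_missing_probe_named_in_error(self):
        beta = BetaMatrix(values=pd.DataFrame({"s": [0.5] * 3}, index=C_PROBES[:3]))
        with pytest.raises(KeyError, match=C_PROBES[3]):
            mlh1_c_region_score(beta, "s")

    def test_probe_order_invariant(self):
        b1 = beta_with_c_region([0.1, 0.2, 0.3, 0.4])
        b2 = BetaMatrix(values=b1.values.iloc[::-1])
        assert mlh1_c_region_score(b1, "s").mean_beta == pytest.approx(
            mlh1_c_region_score(b2, "s").mean_beta
        )


def cimp_beta(region_means, sample="s"):
    """Build a matrix with each CIMP region's probes set to the given mean."""
    panel = registry.cimp_panel()
    probes, vals = [], []
    for gene, plist in panel.items():
        for p in plist:
            probes.append(p)
            vals.append(region_means[gene])
    return BetaMatrix(values=pd.DataFrame({sample: vals}, index=probes))


class TestCimp:
    def test_two_of_five_is_negative(self):
        call = cimp_call(
            cimp_beta({"CACNA1G": 0.5, "RUNX3": 0.5, "SOCS1": 0.1, "NEUROG1": 0.1, "IGF2": 0.1}),
            "s",
        )
        assert call.n_positive_regions == 2
        assert call.status == "negative"

    def test_three_at_boundary_is_high(self):
        call = cimp_call(
            cimp_beta({"CACNA1G": 0.21, "RUNX3": 0.21, "SOCS1": 0.21, "NEUROG1": 0.1, "IGF2": 0.1}),
            "s",
        )
        assert call.n_positive_regions == 3
        assert call.status == "CIMP-high"

    def test_all_unmethylated(self):
        call = cimp_call(cimp_beta(dict.fromkeys(registry.cimp_panel(), 0.01)), "s")
        assert call.n_positive_regions == 0
        assert call.status == "negative"

    def test_monotone_in_any_probe(self):
        base = cimp_beta({"CACNA1G": 0.19, "RUNX3": 0.19, "SOCS1": 0.19, "NEUROG1": 0.19, "IGF2": 0.19})
        n0 = cimp_call(base, "s").n_positive_regions
        for probe in base.probe_ids:
            bumped = BetaMatrix(values=base.values.copy())
            bumped.values.loc[probe, "s"] = 0.9
            assert cimp_call(bumped, "s").n_positive_regions >= n0


class TestRegionMean:
    def test_single_probe_region(self, tiny_beta, tiny_manifest):
        region = Region(name="r", chrom="1", start=100, end=100)
        out = region_mean(tiny_beta, tiny_manifest, region)
        assert out.loc["s1", "mean_beta"] == pytest.approx(0.1)

    def test_empty_region_errors(self, tiny_beta, tiny_manifest):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no probes"):
                region_mean(tiny_beta, tiny_manifest, Region(name="r", chrom="9", start=1, end=2))

    def test_apc_group_means_recover_planted_values(self, default_cohort):
        b = default_cohort
        apc = registry.region("APC_promoter")
        tum = b.sheet.index[(b.sheet.tissue == "tumour")]
        out = region_mean(b.beta, b.manifest, apc, samples=list(tum))
        targets = b.truth.region_targets["apc"]
        for sub, want in (("primary_epimutation", targets["primary_epimutation"]),
                          ("sporadic_methylated", targets["sporadic_methylated"])):
            ids = b.truth.subtype.index[b.truth.subtype == sub]
            got = out.loc[ids, "mean_beta"].mean()
            # per-probe noise SD ~ sqrt(mu(1-mu)/(kappa+1)); group-mean SE is far below 0.03
            assert got == pytest.approx(want, abs=0.03)

    def test_all_16_apc_probes_used(self, default_cohort):
        from epitriage.io import probes_in_region

        probes = probes_in_region(default_cohort.manifest, registry.region("APC_promoter"))
        assert len(probes) == 16


class TestVariableProbes:
    def test_single_high_variance_probe_selected(self):
        vals = pd.DataFrame(
            np.full((10, 4), 0.5), index=[f"p{i}" for i in range(10)], columns=list("abcd")
        )
        vals.loc["p7"] = [0.1, 0.9, 0.1, 0.9]
        sel = select_variable_probes(BetaMatrix(values=vals), fraction=0.1)
        assert sel.probe_ids == ["p7"]
        assert not sel.degenerate

    def test_constant_matrix_tie_policy(self):
        vals = pd.DataFrame(
            np.full((10, 3), 0.4), index=[f"p{i}" for i in range(10)], columns=list("abc")
        )
        sel = select_variable_probes(BetaMatrix(values=vals), fraction=0.3)
        assert sel.probe_ids == ["p0", "p1", "p2"]  # lexicographic tie-break
        assert sel.degenerate

    def test_planted_high_variance_block_recovered(self, rng):
        n, k = 1000, 100
        base = rng.beta(40, 40, size=(n, 12)) * 0.2 + 0.4  # tight around 0.5
        planted = rng.choice(n, size=k, replace=False)
        base[planted] = rng.uniform(0.02, 0.98, size=(k, 12))
        vals = pd.DataFrame(base, index=[f"p{i:04d}" for i in range(n)],
                            columns=[f"s{j}" for j in range(12)])
        sel = select_variable_probes(BetaMatrix(values=vals), fraction=0.1)
        assert set(sel.probe_ids) == {f"p{i:04d}" for i in planted}

    def test_permutation_invariant(self, rng):
        vals = pd.DataFrame(
            rng.uniform(0, 1, (50, 5)), index=[f"p{i:02d}" for i in range(50)],
            columns=[f"s{j}" for j in range(5)],
        )
        sel1 = select_variable_probes(BetaMatrix(values=vals), fraction=0.2)
        shuffled = vals.sample(frac=1, random_state=1).sample(frac=1, axis=1, random_state=2)
        sel2 = select_variable_probes(BetaMatrix(values=shuffled), fraction=0.2)
        assert sel1.probe_ids == sel2.probe_ids

    def test_bad_fraction_rejected(self, tiny_beta):
        with pytest.raises(ValueError):
            select_variable_probes(tiny_beta, fraction=1.5)

    def test_exact_count_mode(self, tiny_beta):
        sel = select_variable_probes(tiny_beta, n_probes=3)
        assert len(sel.probe_ids) == 3
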
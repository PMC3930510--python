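"""Tests of clumping, replication rules, IVW meta-analysis and locus grouping."""

import numpy as np
import pandas as pd
import pytest

from nmrgwas.discovery import (
    LDLookup,
    assess_replication,
    clump_pairs,
    group_loci,
    harmonize_effects,
    ivw_meta,
)
from nmrgwas import gwas
from nmrgwas.simulate import SimConfig, beta_for_variance_explained, simulate_genotypes


def brute_force_clump(hits, snp_r2, feat_r2, r2_snp=0.3, r2_feat=0.4):
    """Independent oracle: explicit greedy absorption on sorted hit list."""
    order = sorted(
        range(len(hits)),
        key=lambda i: (hits[i]["p"], hits[i]["snp_id"], hits[i]["feature_label"]),
    )
    taken = set()
    reps = []
    for i in order:
        if i in taken:
            continue
        taken.add(i)
        reps.append(i)
        for j in order:
            if j in taken:
                continue
            s_ok = snp_r2[(hits[i]["snp_id"], hits[j]["snp_id"])] > r2_snp
            f_ok = feat_r2[(hits[i]["feature_label"], hits[j]["feature_label"])] > r2_feat
            if s_ok and f_ok:
                taken.add(j)
    return sorted(
        (hits[i]["snp_id"], hits[i]["feature_label"]) for i in reps
    )


def _tables(snps, feats, snp_r2, feat_r2):
    ld = pd.DataFrame(1.0, index=snps, columns=snps)
    for (a, b), v in snp_r2.items():
        ld.loc[a, b] = ld.loc[b, a] = v
    fc = pd.DataFrame(1.0, index=feats, columns=feats)
    for (a, b), v in feat_r2.items():
        fc.loc[a, b] = fc.loc[b, a] = v
    return LDLookup(r2_table=ld), fc


class TestClumpPairs:
    def test_single_hit_is_its_own_representative(self):
        hits = pd.DataFrame([{"snp_id": "s1", "feature_label": 1.0, "p": 1e-9}])
        ld, fc = _tables(["s1"], [1.0], {}, {})
        out = clump_pairs(hits, ld, fc)
        assert len(out) == 1 and out["n_members"].iloc[0] == 1

    def test_both_conditions_required(self):
        # same SNP (r2=1) but uncorrelated features: both retained
        hits = pd.DataFrame(
            [
                {"snp_id": "s1", "feature_label": 1.0, "p": 1e-9},
                {"snp_id": "s1", "feature_label": 2.0, "p": 1e-8},
            ]
        )
        ld, fc = _tables(["s1"], [1.0, 2.0], {}, {(1.0, 2.0): 0.2})
        assert len(clump_pairs(hits, ld, fc)) == 2

    def test_chain_structure_matches_brute_force_oracle(self):
        # 8 hits chained via borderline LD/feature links: greedy, not transitive
        snps = [f"s{i}" for i in range(4)]
        feats = [1.0, 2.0, 3.0]
        snp_r2 = {
            ("s0", "s1"): 0.5, ("s1", "s2"): 0.5, ("s0", "s2"): 0.1,
            ("s0", "s3"): 0.9, ("s1", "s3"): 0.2, ("s2", "s3"): 0.6,
        }
        feat_r2 = {(1.0, 2.0): 0.6, (2.0, 3.0): 0.6, (1.0, 3.0): 0.1}
        hits_list = [
            {"snp_id": s, "feature_label": f, "p": p}
            for (s, f, p) in [
                ("s0", 1.0, 1e-12), ("s1", 2.0, 1e-11), ("s2", 3.0, 1e-10),
                ("s3", 1.0, 1e-9), ("s0", 3.0, 1e-8), ("s1", 1.0, 1e-7),
                ("s2", 2.0, 1e-7), ("s3", 3.0, 1e-6),
            ]
        ]
        snp_full = dict(snp_r2)
        for s in snps:
            snp_full[(s, s)] = 1.0
        for (a, b), v in list(snp_r2.items()):
            snp_full[(b, a)] = v
        feat_full = dict(feat_r2)
        for f in feats:
            feat_full[(f, f)] = 1.0
        for (a, b), v in list(feat_r2.items()):
            feat_full[(b, a)] = v
        expected = brute_force_clump(hits_list, snp_full, feat_full)
        ld, fc = _tables(snps, feats, snp_r2, feat_r2)
        out = clump_pairs(pd.DataFrame(hits_list), ld, fc)
        got = sorted(zip(out["snp_id"], out["feature_label"]))
        assert got == expected

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_snp, n_feat = 5, 4
            snps = [f"s{i}" for i in range(n_snp)]
            feats = [round(1.0 + 0.1 * i, 4) for i in range(n_feat)]
            snp_r2, feat_r2 = {}, {}
            for i in range(n_snp):
                for j in range(i + 1, n_snp):
                    snp_r2[(snps[i], snps[j])] = float(rng.random())
            for i in range(n_feat):
                for j in range(i + 1, n_feat):
                    feat_r2[(feats[i], feats[j])] = float(rng.random())
            k = int(rng.integers(2, 10))
            hits_list = [
                {
                    "snp_id": snps[int(rng.integers(n_snp))],
                    "feature_label": feats[int(rng.integers(n_feat))],
                    "p": float(rng.uniform(1e-12, 1e-8)),
                }
                for _ in range(k)
            ]
            # dedupe snp-feature pairs to keep the instance well-posed
            seen = set()
            hits_list = [
                h for h in hits_list
                if (h["snp_id"], h["feature_label"]) not in seen
                and not seen.add((h["snp_id"], h["feature_label"]))
            ]
            snp_full = {**{(s, s): 1.0 for s in snps}}
            for (a, b), v in snp_r2.items():
                snp_full[(a, b)] = snp_full[(b, a)] = v
            feat_full = {**{(f, f): 1.0 for f in feats}}
            for (a, b), v in feat_r2.items():
                feat_full[(a, b)] = feat_full[(b, a)] = v
            expected = brute_force_clump(hits_list, snp_full, feat_full)
            ld, fc = _tables(snps, feats, snp_r2, feat_r2)
            out = clump_pairs(pd.DataFrame(hits_list), ld, fc)
            assert sorted(zip(out["snp_id"], out["feature_label"])) == expected

    def test_no_two_representatives_are_equivalent(self):
        rng = np.random.default_rng(7)
        snps = [f"s{i}" for i in range(6)]
        feats = [round(1.0 + 0.1 * i, 4) for i in range(5)]
        snp_r2 = {
            (snps[i], snps[j]): float(rng.random())
            for i in range(6) for j in range(i + 1, 6)
        }
        feat_r2 = {
            (feats[i], feats[j]): float(rng.random())
            for i in range(5) for j in range(i + 1, 5)
        }
        hits = pd.DataFrame(
            [
                {"snp_id": s, "feature_label": f, "p": float(rng.uniform(1e-12, 1e-8))}
                for s in snps for f in feats
            ]
        )
        ld, fc = _tables(snps, feats, snp_r2, feat_r2)
        out = clump_pairs(hits, ld, fc)
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                both = (
                    ld.r2(out["snp_id"].iloc[i], out["snp_id"].iloc[j]) > 0.3
                    and fc.loc[out["feature_label"].iloc[i], out["feature_label"].iloc[j]] > 0.4
                )
                assert not both

    def test_missing_ld_entry_errors_with_pair_name(self):
        hits = pd.DataFrame(
            [
                {"snp_id": "s1", "feature_label": 1.0, "p": 1e-9},
                {"snp_id": "sX", "feature_label": 1.0, "p": 1e-8},
            ]
        )
        ld, fc = _tables(["s1"], [1.0], {}, {})
        with pytest.raises(KeyError, match="sX"):
            clump_pairs(hits, ld, fc)


class TestIvwMeta:
    def test_equal_effects_equal_se(self):
        m = ivw_meta({"beta": 0.5, "se": 0.1}, {"beta": 0.5, "se": 0.1})
        assert m.x_m == pytest.approx(0.5)
        assert m.se_m == pytest.approx(0.1 / np.sqrt(2))

    def test_plugging_into_the_formula(self):
        m = ivw_meta({"beta": 1.0, "se": 1.0}, {"beta": 0.0, "se": 2.0})
        assert m.x_m == pytest.approx(0.8)
        assert m.se_m == pytest.approx(np.sqrt(0.8))

    def test_combined_effect_lies_between_cohort_effects(self):
        # discovery 0.71 / replication 0.54: the combined effect must lie
        # between them for any positive SEs
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = ivw_meta(
                {"beta": 0.71, "se": float(rng.uniform(0.02, 0.3))},
                {"beta": 0.54, "se": float(rng.uniform(0.02, 0.3))},
            )
            assert 0.54 <= m.x_m <= 0.71

    def test_zero_se_errors(self):
        with pytest.raises(ValueError):
            ivw_meta({"beta": 1.0, "se": 0.0}, {"beta": 1.0, "se": 1.0})

    def test_concordant_similar_effects_strengthen_significance(self):
        from scipy import stats

        grid = [0.2, 0.4, 0.6]
        for xa in grid:
            for xb in grid:
                a = {"beta": xa, "se": 0.1}
                b = {"beta": xb, "se": 0.1}
                m = ivw_meta(a, b)
                pa = 2 * stats.norm.sf(abs(xa) / 0.1)
                pb = 2 * stats.norm.sf(abs(xb) / 0.1)
                assert m.p_m <= max(pa, pb) * (1 + 1e-12)

    def test_allele_harmonization(self):
        flipped, was_flipped, amb = harmonize_effects(0.4, "A", "G", "G", "A")
        assert flipped == -0.4 and was_flipped and not amb
        _, _, amb = harmonize_effects(0.4, "A", "T", "A", "T")
        assert amb
        with pytest.raises(ValueError):
            harmonize_effects(0.4, "A", "G", "C", "T")


class TestAssessReplication:
    def test_discordant_directions_rejected_regardless_of_p(self):
        disc = pd.DataFrame(
            [{"snp_id": "s1", "feature_label": 1.0, "p": 1e-40, "beta": 0.8, "se": 0.05}]
        )
        rep = pd.DataFrame(
            [{"snp_id": "s1", "feature_label": 1.0, "p": 1e-40, "beta": -0.8, "se": 0.05}]
        )
        out = assess_replication(disc, rep, combined_threshold=1e-3)
        assert not out["replicated"].iloc[0] and not out["concordant"].iloc[0]

    def test_unmatched_hit_reported_not_testable(self):
        disc = pd.DataFrame(
            [{"snp_id": "s1", "feature_label": 1.0, "p": 1e-9, "beta": 0.5, "se": 0.1}]
        )
        rep = pd.DataFrame(
            [{"snp_id": "s2", "feature_label": 1.0, "p": 0.5, "beta": 0.1, "se": 0.1}]
        )
        out = assess_replication(disc, rep, combined_threshold=1e-3)
        assert not out["testable"].iloc[0] and not out["replicated"].iloc[0]

    def test_two_cohort_calibration(self):
        """Real effects replicate; false replications are family-wise rare."""
        rng = np.random.default_rng(1)
        n_seeds = 20
        false_any = 0
        true_rates = []
        for _ in range(n_seeds):
            rows_d, rows_r = [], []
            # 20 real hits with strong shared effects, 119 null discovery flukes
            for i in range(139):
                real = i < 20
                beta_true = 0.5 if real else 0.0
                se_d, se_r = 0.05, 0.06
                bd = beta_true + rng.normal(0, se_d)
                br = beta_true + rng.normal(0, se_r)
                from scipy import stats

                rows_d.append(
                    {"snp_id": f"s{i}", "feature_label": 1.0, "beta": bd, "se": se_d,
                     "p": 2 * stats.norm.sf(abs(bd) / se_d)}
                )
                rows_r.append(
                    {"snp_id": f"s{i}", "feature_label": 1.0, "beta": br, "se": se_r,
                     "p": 2 * stats.norm.sf(abs(br) / se_r)}
                )
            out = assess_replication(
                pd.DataFrame(rows_d), pd.DataFrame(rows_r),
                combined_threshold=5.6e-10, n_hits=139,
            )
            true_rates.append(out["replicated"][:20].mean())
            false_any += int(out["replicated"][20:].any())
        assert np.mean(true_rates) > 0.95
        assert false_any / n_seeds <= 0.05 + 0.1  # family-wise false replication rare


class TestGroupLoci:
    def test_distant_snps_form_two_loci(self):
        df = pd.DataFrame(
            [
                {"snp_id": "a", "feature_label": 1.0, "chr": "1", "pos": 1_000_000, "p_m": 1e-10},
                {"snp_id": "b", "feature_label": 1.0, "chr": "1", "pos": 3_000_001, "p_m": 1e-12},
            ]
        )
        assert len(group_loci(df)) == 2

    def test_chain_within_window_is_one_locus(self):
        df = pd.DataFrame(
            [
                {"snp_id": "a", "feature_label": 1.0, "chr": "1", "pos": 1, "p_m": 1e-10},
                {"snp_id": "b", "feature_label": 1.0, "chr": "1", "pos": 900_001, "p_m": 1e-12},
                {"snp_id": "c", "feature_label": 2.0, "chr": "1", "pos": 1_800_001, "p_m": 1e-11},
            ]
        )
        out = group_loci(df)
        assert len(out) == 1
        assert out["lead_snp"].iloc[0] == "b"
        assert out["features"].iloc[0] == [1.0, 2.0]

    def test_lead_tie_broken_by_position(self):
        df = pd.DataFrame(
            [
                {"snp_id": "a", "feature_label": 1.0, "chr": "1", "pos": 500, "p_m": 1e-10},
                {"snp_id": "b", "feature_label": 1.0, "chr": "1", "pos": 100, "p_m": 1e-10},
            ]
        )
        assert group_loci(df)["lead_snp"].iloc[0] == "b"


def test_admixture_narrows_meta_lead_to_short_ld_block():
    """Meta-analysing a long-LD-block cohort with a short-block cohort pulls
    the combined lead SNP into LD with the causal variant in the short-block
    cohort (the locus-narrowing effect of admixed replication panels)."""
    ok = 0
    n_seeds = 10
    for seed in range(n_seeds):
        maf = 0.3
        cfg = SimConfig(
            n_individuals=800, n_snps=40, maf_range=(maf, maf), ld_rho=0.95,
            n_populations=2, block_size=40, seed=700 + seed, n_metabolites=1,
        )
        dos, meta = simulate_genotypes(cfg)
        pops = dos.attrs["population"]
        causal = 20
        beta = beta_for_variance_explained(maf, 0.15)
        rng = np.random.default_rng(1000 + seed)
        y = beta * dos.iloc[:, causal].to_numpy() + rng.normal(0, np.sqrt(0.85), size=len(dos))
        A, B = pops == 0, pops == 1
        res_a = gwas.associate_matrix(y[A], dos.to_numpy()[A])
        res_b = gwas.associate_matrix(y[B], dos.to_numpy()[B])
        p_meta = []
        for j in range(cfg.n_snps):
            if res_a["monomorphic"][j] or res_b["monomorphic"][j]:
                p_meta.append(1.0)
                continue
            m = ivw_meta(
                {"beta": res_a["beta"][0, j], "se": res_a["se"][0, j]},
                {"beta": res_b["beta"][0, j], "se": res_b["se"][0, j]},
            )
            p_meta.append(m.p_m)
        lead = int(np.argmin(p_meta))
        gB = dos.to_numpy()[B]
        r = np.corrcoef(gB[:, lead], gB[:, causal])[0, 1]
        ok += (r * r) > 0.3
    assert ok >= 8
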
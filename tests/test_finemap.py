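"""Association testing, stepwise conditioning, trans-ethnic merging."""

import numpy as np
import pandas as pd
import pytest

import hlaconv as h
from hlaconv.finemap import binary_test, reference_residue


def make_cohort(sim, spec, population="pop1") -> tuple[h.Cohort, "object"]:
    c = h.simulate_cohort(sim, spec)
    return h.Cohort(c.dosage_table(), c.phenotype, c.covariates, population), c


def split_residue(sim, gene="G1"):
    """A causal residue choice: prefer an amino-acid position whose residues
    split the gene's alleles 2/2 (distinct from any single classical allele)."""
    d = sim.aa_dictionary
    alleles = d.alleles(gene)
    for p in d.positions(gene):
        if p == 1:
            continue
        res = [d.residue(gene, a, p) for a in alleles]
        for r in set(res):
            if res.count(r) == 2:
                return p, r
    p = d.positions(gene)[0]
    return p, d.residue(gene, alleles[0], p)


@pytest.fixture(scope="module")
def fm_sim():
    cfg = h.SimConfig(
        n_haplotypes=800,
        n_snvs_per_group=40,
        genes=("G1", "G2"),
        alleles_per_gene={"G1": 4, "G2": 4},
        freq_spectrum={"G1": [0.4, 0.3, 0.2, 0.1], "G2": [0.5, 0.25, 0.15, 0.1]},
        seed=31,
    )
    return h.simulate_reference_panel(cfg)


class TestFilterByCvR2:
    def test_boundary_inclusive(self):
        values = pd.DataFrame({"s1": [1.0, 1.0, 1.0]},
                              index=["v_lo", "v_at", "v_hi"])
        meta = pd.DataFrame(
            {"vclass": "classical_allele", "gene": "G", "position": np.nan,
             "allele": ["01:01", "01:02", "02:01"], "pos_bp": np.nan},
            index=values.index)
        table = h.DosageTable(values, meta)
        kept = h.filter_by_cv_r2(table, {"v_lo": 0.69, "v_at": 0.70, "v_hi": 0.99})
        assert kept == ["v_at", "v_hi"]

    def test_survivor_count_matches_enumeration(self, rng):
        r2 = {f"v{i}": float(x) for i, x in enumerate(rng.random(50))}
        values = pd.DataFrame({"s": np.ones(50)}, index=list(r2))
        meta = pd.DataFrame(
            {"vclass": "residue_binary", "gene": "G", "position": 1,
             "allele": "S", "pos_bp": np.nan}, index=values.index)
        kept = h.filter_by_cv_r2(h.DosageTable(values, meta), r2)
        assert len(kept) == sum(v >= 0.7 for v in r2.values())


class TestLogisticFit:
    def test_two_by_two_closed_form(self):
        # exposure x phenotype table (30, 70; 10, 90)
        x = np.concatenate([np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)])
        y = np.concatenate([np.ones(100), np.zeros(100)])
        fit = h.logistic_fit(x[:, None], y)
        beta = np.log(30 * 90 / (70 * 10))
        se = np.sqrt(1 / 30 + 1 / 70 + 1 / 10 + 1 / 90)
        assert fit.beta[1] == pytest.approx(beta, abs=1e-6)
        assert fit.se[1] == pytest.approx(se, abs=1e-6)
        assert fit.converged

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_optimizer(self, seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        n = 200
        X = rng.normal(size=(n, 3))
        eta = 0.3 + X @ np.array([0.8, -0.5, 0.0])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = h.logistic_fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.se, ref.bse, atol=1e-6)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_balanced_null_has_small_effect(self, rng):
        x = rng.normal(size=300)
        y = (rng.random(300) < 0.5).astype(float)
        fit = h.logistic_fit(x[:, None], y)
        assert abs(fit.beta[0]) < 0.3
        assert abs(fit.beta[1] / fit.se[1]) < 3.5

    def test_separation_flagged_not_raised(self):
        x = np.concatenate([np.ones(20), np.zeros(20)])
        y = x.copy()
        fit = h.logistic_fit(x[:, None], y)
        assert fit.separated[1]
        assert np.isnan(fit.wald_p("x0"))

    def test_aliased_column_dropped(self, rng):
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = (rng.random(100) < 0.5).astype(float)
        fit = h.logistic_fit(X, y)
        assert fit.dropped == ["b"]


class TestOmnibus:
    def test_two_residue_position_reduces_to_binary_lrt(self, fm_sim):
        spec = h.CohortSpec(n_cases=150, n_controls=150, seed=4)
        cohort, _ = make_cohort(fm_sim, spec)
        # find a k=2 position
        table = cohort.dosages
        gene, pos = None, None
        for p in fm_sim.aa_dictionary.positions("G1"):
            if len(table.position_residues("G1", p)) == 2:
                gene, pos = "G1", p
                break
        assert gene is not None
        res = h.omnibus_test(cohort, gene, pos, [])
        assert res.df == 1
        # manual single-column LRT
        ref = reference_residue(table, gene, pos)
        other = [i for i in table.position_residues(gene, pos) if i != ref][0]
        base = h.logistic_fit(cohort.covariates, cohort.phenotype)
        full = h.logistic_fit(
            cohort.covariates.assign(d=table.values.loc[other].to_numpy()),
            cohort.phenotype)
        from scipy import stats
        p_manual = stats.chi2.sf(2 * (full.loglik - base.loglik), 1)
        assert res.p_value == pytest.approx(p_manual, abs=1e-10)

    def test_planted_residue_reaches_genome_wide_significance(self, fm_sim):
        pos, residue = split_residue(fm_sim)
        spec = h.CohortSpec(
            n_cases=600, n_controls=600,
            causal_effects={("residue", "G1", pos, residue): 1.0},
            intercept=-1.0, seed=7)
        cohort, _ = make_cohort(fm_sim, spec)
        res = h.omnibus_test(cohort, "G1", pos, [])
        assert res.p_value < 5e-8

    def test_single_residue_position_skipped(self, fm_sim):
        spec = h.CohortSpec(n_cases=50, n_controls=50, seed=5)
        cohort, _ = make_cohort(fm_sim, spec)
        keep = [v for v in cohort.dosages.values.index if v != "AA_G1_1_A"]
        sub = h.DosageTable(cohort.dosages.values.loc[keep],
                            cohort.dosages.meta.loc[keep])
        # drop all but one residue at position 1 of G1
        pos1 = [v for v in keep if v.startswith("AA_G1_1_")]
        keep2 = [v for v in keep if not v.startswith("AA_G1_1_") or v == pos1[0]]
        sub = h.DosageTable(sub.values.loc[keep2], sub.meta.loc[keep2])
        cohort2 = h.Cohort(sub, cohort.phenotype, cohort.covariates)
        res = h.omnibus_test(cohort2, "G1", 1, [])
        assert res.flagged and "fewer than 2" in res.note


class TestConditioningSet:
    def test_gene_level_drops_reference_allele(self, fm_sim):
        spec = h.CohortSpec(n_cases=40, n_controls=40, seed=6)
        cohort, _ = make_cohort(fm_sim, spec)
        cols = h.conditioning_set(cohort.dosages, ("gene", "G1"))
        assert len(cols) == 3  # 4 alleles minus the reference
        assert all(c.startswith("HLA_G1_") for c in cols)

    def test_position_level_k_minus_one(self, fm_sim):
        spec = h.CohortSpec(n_cases=40, n_controls=40, seed=6)
        cohort, _ = make_cohort(fm_sim, spec)
        ids = cohort.dosages.position_residues("G1", 1)
        cols = h.conditioning_set(cohort.dosages, ("position", "G1", 1))
        assert len(cols) == len(ids) - 1

    def test_variant_level_single_column_and_dedupe(self, fm_sim):
        spec = h.CohortSpec(n_cases=40, n_controls=40, seed=6)
        cohort, _ = make_cohort(fm_sim, spec)
        vid = cohort.dosages.values.index[0]
        assert h.conditioning_set(cohort.dosages, ("variant", vid)) == [vid]
        from hlaconv.finemap import dedupe
        assert dedupe([vid, vid, "x"]) == [vid, "x"]


class TestStepwise:
    def test_planted_signal_recovered_then_stops(self, fm_sim):
        pos, residue = split_residue(fm_sim)
        spec = h.CohortSpec(
            n_cases=600, n_controls=600,
            causal_effects={("residue", "G1", pos, residue): 1.0},
            intercept=-1.0, seed=11)
        cohort, raw = make_cohort(fm_sim, spec)
        state = h.stepwise_conditional(cohort, tight_ld_genes=("G1", "G2"))
        assert len(state.selected) >= 1
        causal = raw.true_residue_dosage("G1", pos, residue)
        first = state.rounds[0]
        assert first.p_value < 5e-8
        # the selected signal tags the causal dosage almost perfectly
        if first.test == "binary":
            sel_dose = cohort.dosages.values.loc[first.selected].to_numpy()
            assert abs(np.corrcoef(causal, sel_dose)[0, 1]) > 0.95
        else:
            assert first.selected == f"AA_G1_{pos}"
        assert "above threshold" in state.stopping_reason or len(state.selected) == 1

    def test_null_phenotype_yields_zero_rounds(self, fm_sim):
        spec = h.CohortSpec(n_cases=300, n_controls=300, intercept=0.0, seed=12)
        cohort, _ = make_cohort(fm_sim, spec)
        state = h.stepwise_conditional(cohort)
        assert state.selected == []
        assert "above threshold" in state.stopping_reason

    def test_empty_variant_list(self, fm_sim):
        spec = h.CohortSpec(n_cases=20, n_controls=20, seed=13)
        cohort, _ = make_cohort(fm_sim, spec)
        state = h.stepwise_conditional(cohort, variant_ids=[])
        assert state.rounds == [] and "no variants" in state.stopping_reason

    def test_output_invariant_to_variant_order(self, fm_sim):
        pos, residue = split_residue(fm_sim)
        spec = h.CohortSpec(
            n_cases=400, n_controls=400,
            causal_effects={("residue", "G1", pos, residue): 0.9},
            intercept=-0.8, seed=14)
        cohort, _ = make_cohort(fm_sim, spec)
        ids = list(cohort.dosages.values.index)
        a = h.stepwise_conditional(cohort, ids)
        b = h.stepwise_conditional(cohort, ids[::-1])
        assert a.selected == b.selected


class TestTransethnicMerge:
    def _two_cohorts(self):
        rng = np.random.default_rng(0)

        def cohort(tag, pop, extra_allele=False):
            n = 30
            ids = [f"{tag}{i}" for i in range(n)]
            rows = {
                "HLA_G1_0101": rng.random(n) * 2,
                "AA_G1_2_S": rng.random(n) * 2,
                "snv_pal": rng.integers(0, 3, n).astype(float),
                "snv_ok": rng.integers(0, 3, n).astype(float),
            }
            meta = {
                "HLA_G1_0101": ("classical_allele", "G1", np.nan, "01:01"),
                "AA_G1_2_S": ("residue_binary", "G1", 2.0, "S"),
                "snv_pal": ("snv", "", np.nan, "A>T"),
                "snv_ok": ("snv", "", np.nan, "A>G"),
            }
            if extra_allele:
                rows["HLA_G1_0202"] = rng.random(n) * 2
                meta["HLA_G1_0202"] = ("classical_allele", "G1", np.nan, "02:02")
            values = pd.DataFrame(rows, index=ids).T
            mdf = pd.DataFrame(
                [meta[k] for k in values.index],
                columns=["vclass", "gene", "position", "allele"],
                index=values.index,
            )
            mdf["pos_bp"] = np.nan
            cov = pd.DataFrame(
                {"sex": rng.integers(0, 2, n).astype(float),
                 "PC1": rng.normal(size=n), "PC2": rng.normal(size=n)},
                index=ids)
            y = rng.integers(0, 2, n)
            return h.Cohort(h.DosageTable(values, mdf), y, cov, population=pop)

        return cohort("a", "JP", extra_allele=True), cohort("b", "EU")

    def test_structure_of_merged_design(self):
        c1, c2 = self._two_cohorts()
        merged = h.transethnic_merge([c1, c2])
        # palindromic SNV removed, shared SNV kept
        assert "snv_pal" not in merged.dosages.values.index
        assert "snv_ok" in merged.dosages.values.index
        # allele private to cohort 1 zero-filled for cohort 2
        private = merged.dosages.values.loc["HLA_G1_0202"]
        assert (private[c2.sample_ids] == 0.0).all()
        assert (private[c1.sample_ids] == c1.dosages.values.loc["HLA_G1_0202"]).all()
        # PCs block-diagonal: JP PCs zero on EU rows and vice versa
        assert (merged.covariates.loc[c2.sample_ids, "JP_PC1"] == 0.0).all()
        assert (merged.covariates.loc[c1.sample_ids, "EU_PC2"] == 0.0).all()
        # population indicator
        assert (merged.covariates.loc[c2.sample_ids, "pop_EU"] == 1.0).all()
        assert (merged.covariates.loc[c1.sample_ids, "pop_EU"] == 0.0).all()

    def test_duplicate_sample_ids_rejected(self):
        c1, _ = self._two_cohorts()
        with pytest.raises(ValueError, match="duplicate"):
            h.transethnic_merge([c1, c1])

    def test_shared_signal_gains_significance_when_merged(self):
        cfg = h.SimConfig(
            n_haplotypes=800, n_snvs_per_group=30, genes=("G1",),
            alleles_per_gene={"G1": 4},
            freq_spectrum={"G1": [0.4, 0.3, 0.2, 0.1]},
            n_populations=2, pop_divergence=0.6, seed=41)
        sim = h.simulate_reference_panel(cfg)
        pos, residue = split_residue(sim)
        vid = f"AA_G1_{pos}_{residue}"
        pvals = {}
        cohorts = []
        for pop, seed in (("pop1", 1), ("pop2", 2)):
            spec = h.CohortSpec(
                n_cases=250, n_controls=250,
                causal_effects={("residue", "G1", pos, residue): 0.7},
                intercept=-0.8, seed=seed)
            c = h.simulate_cohort(sim, spec)
            mask = c.population == pop
            keep = np.flatnonzero(mask)
            table = c.dosage_table()
            cohort = h.Cohort(
                h.DosageTable(table.values.iloc[:, keep],
                              table.meta),
                c.phenotype[keep],
                c.covariates.iloc[keep],
                population=pop)
            cohorts.append(cohort)
            pvals[pop] = binary_test(cohort, vid, []).p_value
        # re-key sample ids to avoid collisions across the two draws
        c2 = cohorts[1]
        new_ids = [f"x_{s}" for s in c2.sample_ids]
        c2.dosages.values.columns = new_ids
        c2.covariates.index = new_ids
        merged = h.transethnic_merge(cohorts)
        p_merged = binary_test(merged, vid, []).p_value
        assert p_merged < min(pvals.values())


class TestVarianceExplained:
    def _toy_table(self, x):
        values = pd.DataFrame({f"s{i}": [x[i]] for i in range(len(x))},
                              index=["v"])
        meta = pd.DataFrame({"vclass": "classical_allele", "gene": "G",
                             "position": np.nan, "allele": "01:01",
                             "pos_bp": np.nan}, index=["v"])
        return h.DosageTable(values, meta)

    def test_zero_effects_explain_nothing(self, rng):
        x = rng.integers(0, 3, 100).astype(float)
        y = rng.integers(0, 2, 100)
        assert h.variance_explained({"v": 0.0}, self._toy_table(x), y, 0.01) == 0.0

    def test_invariant_to_effect_scaling_sign(self, rng):
        x = rng.integers(0, 3, 200).astype(float)
        y = (rng.random(200) < 1 / (1 + np.exp(-0.5 * x))).astype(int)
        t = self._toy_table(x)
        a = h.variance_explained({"v": 0.7}, t, y, 0.05)
        b = h.variance_explained({"v": -0.7}, t, y, 0.05)
        assert a == pytest.approx(b)

    def test_prevalence_bounds(self, rng):
        x = rng.integers(0, 3, 50).astype(float)
        y = rng.integers(0, 2, 50)
        with pytest.raises(ValueError):
            h.variance_explained({"v": 1.0}, self._toy_table(x), y, 1.5)

    def test_matches_direct_liability_simulation(self):
        """Single-variant toy model: draw liabilities, threshold at K, sample
        a case-control set, and compare the liability-scale estimate with the
        generative variance explained."""
        rng = np.random.default_rng(77)
        K, f, b = 0.05, 0.3, 0.4
        n_pop = 400_000
        x = rng.binomial(2, f, n_pop).astype(float)
        liab = b * (x - x.mean()) / x.std() + rng.normal(size=n_pop)
        thr = np.quantile(liab, 1 - K)
        y = (liab > thr).astype(int)
        h2_true = b**2 / (b**2 + 1)
        cases = np.flatnonzero(y == 1)[:3000]
        controls = np.flatnonzero(y == 0)[:3000]
        idx = np.concatenate([cases, controls])
        xs, ys = x[idx], y[idx]
        fit = h.logistic_fit(xs[:, None], ys)
        est = h.variance_explained({"v": float(fit.beta[1])},
                                   self._toy_table(xs), ys, K)
        assert est == pytest.approx(h2_true, rel=0.35)
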
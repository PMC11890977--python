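import numpy as np
import pytest

import sfcoupling as sf
from sfcoupling.datatypes import AnalysisConfig
from sfcoupling.io import validate_cohort
from sfcoupling.networks import fisher_z, pearson_fc
from sfcoupling.coupling import subject_coupling
from sfcoupling.simulate import (
    SimulationParams,
    generate_cohort,
    make_structural_template,
    sample_cognition,
    sample_subject_bold,
    sample_subject_sc,
)


def test_default_design_matches_the_emulated_study():
    p = SimulationParams()
    assert (p.n_hc, p.n_vci, p.n_nodes, p.n_timepoints) == (53, 68, 90, 200)


def test_parameter_validation():
    with pytest.raises(ValueError, match="backbone_k"):
        SimulationParams(n_nodes=10, backbone_k=10)
    with pytest.raises(ValueError, match="base \\+ boost"):
        SimulationParams(coupling_base=0.8, coupling_boost=0.3)
    with pytest.raises(ValueError, match="boost_nodes"):
        SimulationParams(n_nodes=20, backbone_k=4, boost_nodes=(25,))


class TestStructuralTemplate:
    def test_same_seed_gives_identical_templates(self):
        p = SimulationParams(n_nodes=30, backbone_k=6, seed=5)
        np.testing.assert_array_equal(
            make_structural_template(p, "HC"), make_structural_template(p, "HC")
        )

    def test_zero_deficit_makes_groups_identical(self):
        p = SimulationParams(n_nodes=30, backbone_k=6, seed=5, vci_structural_deficit=0.0)
        np.testing.assert_array_equal(
            make_structural_template(p, "HC"), make_structural_template(p, "VCI")
        )

    def test_deficit_strictly_lowers_strength_at_deficit_nodes(self):
        p = SimulationParams(n_nodes=30, backbone_k=6, seed=5, vci_structural_deficit=0.5)
        hc = make_structural_template(p, "HC")
        vci = make_structural_template(p, "VCI")
        for node in p.deficit_nodes:
            assert vci[node].sum() < hc[node].sum()
        untouched = [i for i in range(30) if i not in p.deficit_nodes]
        # non-deficit rows only change through their edges into deficit nodes
        keep = np.ix_(untouched, untouched)
        np.testing.assert_array_equal(hc[keep], vci[keep])


@pytest.fixture(scope="module")
def template_and_params():
    p = SimulationParams(n_nodes=30, backbone_k=6, seed=5)
    return make_structural_template(p, "HC"), p


@pytest.fixture(scope="module")
def subject_sc():
    p = SimulationParams(n_nodes=40, backbone_k=8, seed=9)
    tpl = make_structural_template(p, "HC")
    return sample_subject_sc(tpl, p, np.random.default_rng(3)), p


class TestSubjectSC:
    def test_zero_template_edges_stay_zero(self, template_and_params):
        tpl, p = template_and_params
        sc = sample_subject_sc(tpl, p, np.random.default_rng(0))
        assert np.all(sc.values[tpl == 0] == 0)

    def test_counts_are_unbiased_for_the_template_mean(self, template_and_params):
        tpl, p = template_and_params
        i, j = np.argwhere(tpl > 0)[0]
        mu = tpl[i, j]
        rng = np.random.default_rng(1)
        draws = np.array([sample_subject_sc(tpl, p, rng).values[i, j] for _ in range(500)])
        # NB variance mu + mu^2/r
        se = np.sqrt((mu + mu**2 / p.count_dispersion) / 500)
        assert abs(draws.mean() - mu) < 3 * se

    def test_matrix_invariants_hold(self, template_and_params):
        tpl, p = template_and_params
        sc = sample_subject_sc(tpl, p, np.random.default_rng(2))
        v = sc.values
        assert np.all(v >= 0) and np.all(v == np.round(v))
        np.testing.assert_array_equal(v, v.T)
        assert np.all(np.diagonal(v) == 0)


class TestSubjectBOLD:
    def _mean_rho(self, sc, mixing, n_timepoints, seed):
        bold = sample_subject_bold(sc, mixing, n_timepoints, np.random.default_rng(seed))
        z, _ = fisher_z(pearson_fc(bold, node_labels=sc.node_labels))
        prof = subject_coupling(sc, z, AnalysisConfig(min_coupling_pairs=3))
        return float(np.nanmean(prof.rho))

    def test_full_mixing_recovers_high_coupling(self, subject_sc):
        sc, _ = subject_sc
        assert self._mean_rho(sc, np.ones(40), 2000, seed=11) > 0.8

    def test_zero_mixing_gives_null_coupling(self, subject_sc):
        sc, _ = subject_sc
        assert abs(self._mean_rho(sc, np.zeros(40), 2000, seed=12)) < 0.1

    def test_same_seed_reproduces_series(self, subject_sc):
        sc, _ = subject_sc
        b1 = sample_subject_bold(sc, np.full(40, 0.5), 50, np.random.default_rng(7))
        b2 = sample_subject_bold(sc, np.full(40, 0.5), 50, np.random.default_rng(7))
        np.testing.assert_array_equal(b1, b2)

    def test_mixing_validation(self, subject_sc):
        sc, _ = subject_sc
        with pytest.raises(ValueError, match="one weight per node"):
            sample_subject_bold(sc, np.ones(5), 50, np.random.default_rng(0))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            sample_subject_bold(sc, np.full(40, 1.5), 50, np.random.default_rng(0))


class TestCognition:
    def test_null_effect_gives_near_zero_correlation(self):
        p = SimulationParams(cognition_effect=0.0, seed=0)
        rng = np.random.default_rng(0)
        couplings = rng.uniform(0.2, 0.8, size=200)
        scores = np.array(
            [sample_cognition(68.0, 10.0, c, p, rng)["AVLT"] for c in couplings]
        )
        assert abs(np.corrcoef(couplings, scores)[0, 1]) < 0.15

    def test_negative_effect_is_monotone_in_the_noiseless_limit(self):
        p = SimulationParams(cognition_effect=-30.0, noise_sd=1e-12, seed=0)
        rng = np.random.default_rng(0)
        values = [
            sample_cognition(68.0, 10.0, c, p, rng)["SDMT"] for c in (0.2, 0.5, 0.8)
        ]
        assert values[0] > values[1] > values[2]

    def test_same_seed_reproduces_scores(self):
        p = SimulationParams(seed=0)
        s1 = sample_cognition(68.0, 10.0, 0.5, p, np.random.default_rng(1))
        s2 = sample_cognition(68.0, 10.0, 0.5, p, np.random.default_rng(1))
        assert s1 == s2


class TestGenerateCohort:
    def test_default_cohort_matches_study_design(self):
        cohort, truth = generate_cohort(SimulationParams(seed=42))
        assert len(cohort.subjects) == 121
        groups = [s.group for s in cohort.subjects]
        assert groups.count("VCI") == 68 and groups.count("HC") == 53
        sid = cohort.subject_ids[0]
        assert cohort.sc_matrices[sid].n_nodes == 90
        assert cohort.bold_series[sid].shape == (90, 200)
        assert set(truth.mixing) == set(cohort.subject_ids)

    def test_small_cohort_passes_validation(self):
        p = SimulationParams(n_nodes=20, backbone_k=4, n_hc=3, n_vci=3, n_timepoints=30, seed=1)
        cohort, _ = generate_cohort(p)
        assert validate_cohort(cohort) == []

    def test_full_determinism_under_fixed_seed(self, small_params):
        c1, t1 = generate_cohort(small_params)
        c2, t2 = generate_cohort(small_params)
        for sid in c1.subject_ids:
            np.testing.assert_array_equal(c1.sc_matrices[sid].values, c2.sc_matrices[sid].values)
            np.testing.assert_array_equal(c1.bold_series[sid], c2.bold_series[sid])
            np.testing.assert_array_equal(t1.mixing[sid], t2.mixing[sid])
        for s1, s2 in zip(c1.subjects, c2.subjects):
            assert s1 == s2

    def test_planted_mixing_pattern(self, small_cohort, small_params):
        cohort, truth = small_cohort
        p = small_params
        for s in cohort.subjects:
            m = truth.mixing[s.subject_id]
            if s.group == "VCI":
                assert np.allclose(m[list(p.boost_nodes)], p.coupling_base + p.coupling_boost)
            else:
                assert np.allclose(m, p.coupling_base)

    def test_boost_raises_estimated_group_coupling_difference(self):
        """Mean estimated VCI-HC coupling difference at boost nodes grows
        with the planted boost (0 vs 0.3)."""
        diffs = []
        for boost in (0.0, 0.3):
            p = SimulationParams(
                n_nodes=30, backbone_k=6, n_hc=8, n_vci=8, n_timepoints=300,
                coupling_boost=boost, vci_structural_deficit=0.0, seed=77,
            )
            cohort, truth = generate_cohort(p)
            cfg = AnalysisConfig(min_coupling_pairs=3)
            rho = {"HC": [], "VCI": []}
            for s in cohort.subjects:
                sc = cohort.sc_matrices[s.subject_id]
                z, _ = fisher_z(pearson_fc(cohort.bold_series[s.subject_id], node_labels=sc.node_labels))
                prof = subject_coupling(sc, z, cfg)
                rho[s.group].append(np.nanmean(prof.rho[list(p.boost_nodes)]))
            diffs.append(np.mean(rho["VCI"]) - np.mean(rho["HC"]))
        assert diffs[1] > diffs[0]
        assert diffs[1] > 0.05
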
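"""Synthetic cohort generator: covariance construction, membership
assignment, timeseries sampling and phenotype simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fcgroups.atlas import GROUP_TEMPLATES, NETWORKS, block_sign, default_node_network_map
from fcgroups.cohort import (
    PlantedGroup,
    SimConfig,
    assign_members,
    build_covariance,
    default_planted_groups,
    generate_cohort,
    simulate_phenotypes,
    simulate_timeseries,
    template_affinity,
)


def _toy_config(**kw):
    defaults = dict(n_controls=4, n_sz=3, n_bp=3, n_nodes=16, n_timepoints=50)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestBuildCovariance:
    def test_no_groups_gives_baseline_blocks(self):
        cfg = _toy_config(n_nodes=32)
        cov = build_covariance(cfg, [])
        nets = np.asarray(cfg.resolve_node_map())
        same = nets[:, None] == nets[None, :]
        off_diag = ~np.eye(32, dtype=bool)
        assert np.allclose(cov[same & off_diag], cfg.rho_within, atol=1e-9)
        assert np.allclose(cov[~same], cfg.rho_between, atol=1e-9)
        assert np.allclose(np.diag(cov), 1.0)

    def test_bold_block_shift(self):
        # a group raising DMN connectivity strongly: DMN-DMN off-diagonal
        # entries move to rho_within + delta_bold (no PSD repair needed here)
        cfg = _toy_config(n_nodes=32)
        g = PlantedGroup(
            name="g", member_ids=("SZ001",),
            network_signs={"DMN": (+1, True)}, tci_profile={}, clinical_profile={},
        )
        cov = build_covariance(cfg, [g])
        nets = np.asarray(cfg.resolve_node_map())
        dmn = nets == "DMN"
        blk = cov[np.ix_(dmn, dmn)]
        off = ~np.eye(blk.shape[0], dtype=bool)
        assert np.allclose(blk[off], cfg.rho_within + cfg.delta_bold, atol=1e-6)

    def test_three_network_toy_matches_hand_computation(self):
        # one "+" within-block and one "-" within-block; the brute-force
        # eigenvalue oracle confirms validity after repair
        node_map = ["DMN"] * 2 + ["CON"] * 2 + ["FPN"] * 2
        cfg = _toy_config(n_nodes=6, node_network_map=node_map)
        g = PlantedGroup(
            name="g", member_ids=("SZ001",),
            network_signs={"DMN": (+1, False), "CON": (-1, False)},
            tci_profile={}, clinical_profile={},
        )
        cov = build_covariance(cfg, [g])
        assert cov[0, 1] == pytest.approx(0.35 + 0.12, abs=1e-6)
        assert cov[2, 3] == pytest.approx(0.35 - 0.12, abs=1e-6)
        assert cov[4, 5] == pytest.approx(0.35, abs=1e-6)
        # DMN-CON cross block: opposite signs cancel to baseline
        assert cov[0, 2] == pytest.approx(0.10, abs=1e-6)
        assert np.linalg.eigvalsh(cov).min() >= 1e-6 - 1e-12

    def test_invalid_network_label_rejected(self):
        cfg = _toy_config()
        g = PlantedGroup(
            name="g", member_ids=(), network_signs={"NOPE": (+1, False)},
            tci_profile={}, clinical_profile={},
        )
        with pytest.raises(ValueError, match="invalid network"):
            build_covariance(cfg, [g])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_every_generated_covariance_is_valid(self, seed):
        rng = np.random.default_rng(seed)
        templates = list(GROUP_TEMPLATES)
        groups = [
            PlantedGroup(
                name=t.name, member_ids=(), network_signs=dict(t.network_signs),
                tci_profile={}, clinical_profile={},
            )
            for t in templates
        ]
        combo = [groups[i] for i in rng.choice(5, size=2, replace=False)]
        cov = build_covariance(_toy_config(n_nodes=48), combo)
        assert np.allclose(cov, cov.T)
        assert np.allclose(np.diag(cov), 1.0)
        assert np.linalg.eigvalsh(cov).min() >= -1e-8


class TestSimulateTimeseries:
    def test_identity_covariance_sample_correlations_near_zero(self):
        ts = simulate_timeseries(np.eye(30), 2000, seed=7)
        corr = np.corrcoef(ts, rowvar=False)
        off = corr[np.triu_indices(30, k=1)]
        # Fisher-z CI: at T=2000 essentially all |r| < 0.15
        assert np.mean(np.abs(off) < 0.15) >= 0.99

    def test_deterministic_under_seed(self):
        cov = build_covariance(_toy_config(n_nodes=16), [])
        a = simulate_timeseries(cov, 100, seed=3)
        b = simulate_timeseries(cov, 100, seed=3)
        assert np.array_equal(a, b)

    def test_block_correlation_recovered_within_sampling_error(self):
        # r=0.8 block, T=2000: Fisher-z sampling SD = 1/sqrt(T-3) ~ 0.022
        cov = np.full((6, 6), 0.8)
        np.fill_diagonal(cov, 1.0)
        ts = simulate_timeseries(cov, 2000, seed=11)
        corr = np.corrcoef(ts, rowvar=False)
        off = corr[np.triu_indices(6, k=1)]
        assert 0.75 <= off.mean() <= 0.85

    def test_non_psd_raises_with_hint(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="repair"):
            simulate_timeseries(bad, 10, seed=0)


class TestMembershipAssignment:
    def test_default_groups_reproduce_reference_sizes(self):
        sz = [f"SZ{i:03d}" for i in range(27)]
        bp = [f"BP{i:03d}" for i in range(35)]
        groups = default_planted_groups(sz, bp)
        sizes = [len(g.member_ids) for g in groups]
        assert sizes == [11, 27, 10, 35, 16]
        per_sz = [sum(m.startswith("SZ") for m in g.member_ids) for g in groups]
        per_bp = [sum(m.startswith("BP") for m in g.member_ids) for g in groups]
        assert per_sz == [5, 10, 4, 17, 8]
        assert per_bp == [6, 17, 6, 18, 8]

    def test_every_patient_covered_and_overlap_present(self):
        sz = [f"SZ{i:03d}" for i in range(27)]
        bp = [f"BP{i:03d}" for i in range(35)]
        groups = default_planted_groups(sz, bp)
        union = set().union(*(set(g.member_ids) for g in groups))
        assert union == set(sz) | set(bp)
        total = sum(len(g.member_ids) for g in groups)
        assert total == 99  # fuzzy overlap: more memberships than patients

    def test_each_group_keeps_unique_members(self):
        sz = [f"SZ{i:03d}" for i in range(27)]
        bp = [f"BP{i:03d}" for i in range(35)]
        groups = default_planted_groups(sz, bp)
        for g in groups:
            others = set().union(
                *(set(h.member_ids) for h in groups if h is not g)
            )
            assert set(g.member_ids) - others, f"{g.name} has no unique member"

    def test_pairwise_jaccard_below_dedup_threshold(self):
        sz = [f"SZ{i:03d}" for i in range(27)]
        bp = [f"BP{i:03d}" for i in range(35)]
        groups = default_planted_groups(sz, bp)
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                sa, sb = set(a.member_ids), set(b.member_ids)
                assert len(sa & sb) / len(sa | sb) < 0.6

    def test_assignment_is_deterministic(self):
        ids = [f"P{i}" for i in range(20)]
        aff = template_affinity(GROUP_TEMPLATES)
        a = assign_members(ids, [4, 9, 4, 11, 5], aff)
        b = assign_members(ids, [4, 9, 4, 11, 5], aff)
        assert a == b

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError):
            assign_members(["a", "b", "c"], [1, 1])  # cannot cover everyone


class TestPhenotypes:
    def _cohort_frame(self, n_c=10, n_sz=10, n_bp=10):
        ids = ([f"C{i}" for i in range(n_c)] + [f"SZ{i}" for i in range(n_sz)]
               + [f"BP{i}" for i in range(n_bp)])
        status = ["control"] * n_c + ["SZ"] * n_sz + ["BP"] * n_bp
        return pd.DataFrame({"subject_id": ids, "status": status})

    def test_zero_effect_gives_exchangeable_scores(self):
        cfg = _toy_config(tci_effect=0.0)
        frame = self._cohort_frame()
        g = PlantedGroup(
            name="g", member_ids=tuple(f"SZ{i}" for i in range(10)),
            network_signs={}, tci_profile={"HA": +1}, clinical_profile={},
        )
        diffs = []
        for seed in range(50):
            out = simulate_phenotypes(frame, [g], cfg, seed=seed)
            mem = out["subject_id"].isin(g.member_ids)
            diffs.append(out.loc[mem, "HA"].mean() - out.loc[~mem, "HA"].mean())
        assert abs(np.mean(diffs)) < 0.15  # zero in expectation

    def test_group1_profile_separates_ha_with_planned_power(self):
        # d = 1.5 at >= 10 per arm: two-sample t significant at p < 0.01 with
        # power ~0.9+, so nearly all seeds must reject
        cfg = _toy_config(tci_effect=1.5)
        frame = self._cohort_frame(n_c=0, n_sz=15, n_bp=15)
        g = PlantedGroup(
            name="g", member_ids=tuple(f"SZ{i}" for i in range(15)),
            network_signs={}, tci_profile={"HA": +1, "SD": -1}, clinical_profile={},
        )
        hits = 0
        for seed in range(100):
            out = simulate_phenotypes(frame, [g], cfg, seed=seed)
            mem = out["subject_id"].isin(g.member_ids)
            p = sps.ttest_ind(out.loc[mem, "HA"], out.loc[~mem, "HA"]).pvalue
            hits += p < 0.01
        assert hits >= 90

    def test_demographics_are_group_balanced(self):
        cfg = _toy_config()
        frame = self._cohort_frame(n_c=0, n_sz=20, n_bp=20)
        g = PlantedGroup(
            name="g", member_ids=tuple(f"SZ{i}" for i in range(20)),
            network_signs={}, tci_profile={}, clinical_profile={},
        )
        hits = 0
        for seed in range(100):
            out = simulate_phenotypes(frame, [g], cfg, seed=seed)
            mem = out["subject_id"].isin(g.member_ids)
            tab = pd.crosstab(mem, out["sex"])
            if tab.shape == (2, 2):
                _, p, _, _ = sps.chi2_contingency(tab)
            else:
                p = 1.0
            hits += p > 0.05
        assert hits >= 90


class TestGenerateCohort:
    def test_ground_truth_withheld_from_written_roster(self, tmp_path):
        from fcgroups.cohort import write_cohort

        cfg = _toy_config(n_nodes=16, n_timepoints=20)
        sim = generate_cohort(cfg, seed=5)
        paths = write_cohort(sim, tmp_path)
        roster = pd.read_csv(paths["cohort"])
        assert "planted_memberships" not in roster.columns
        assert paths["ground_truth"].exists()

    def test_roundtrip_through_disk(self, tmp_path):
        from fcgroups.cohort import write_cohort
        from fcgroups.pipeline import load_cohort_dir

        cfg = _toy_config(n_nodes=16, n_timepoints=20)
        sim = generate_cohort(cfg, seed=5)
        write_cohort(sim, tmp_path)
        back = load_cohort_dir(tmp_path)
        assert back.subject_ids == sim.subject_ids
        sid = sim.subject_ids[0]
        assert np.allclose(back.timeseries[sid], sim.timeseries[sid], atol=1e-5)
        assert back.memberships == sim.memberships

    def test_controls_have_no_membership(self):
        cfg = _toy_config(n_nodes=16, n_timepoints=20)
        sim = generate_cohort(cfg, seed=2)
        members = set().union(*(set(v) for v in sim.memberships.values()))
        assert not members & set(sim.control_ids)


def test_block_sign_lifting_rules():
    t = GROUP_TEMPLATES[3]  # mixed-sign template
    assert block_sign(t, "CON", "CON") == (-1, True)
    assert block_sign(t, "FPN", "DAN") == (+1, False)  # same sign, not both bold
    assert block_sign(t, "FPN", "CON") == (0, False)  # conflicting signs
    assert block_sign(t, "SAL", "SAL") == (0, False)  # unlisted network


def test_default_node_map_even_partition():
    m = default_node_network_map(160)
    assert len(m) == 160
    counts = pd.Series(m).value_counts()
    assert set(counts) == {10}
    with pytest.raises(ValueError):
        default_node_network_map(8)
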
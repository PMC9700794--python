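"""Synthetic cohort generator: topologies, determinism, ground-truth recovery."""

import numpy as np
import pytest

from socialdrift.cohort import (
    CohortConfig,
    DEFAULT_ARCHETYPES,
    build_topology,
    default_experiment_configs,
    generate_cohort,
)
from socialdrift.data import (
    MNIPD_MATRIX,
    PIPD_MATRIX,
    TreatmentSpec,
    records_to_frame,
    write_records,
)
from socialdrift.pipeline import build_cohort_table
from socialdrift.ra import cohort_ra
from socialdrift.stats import spearman


class TestTopology:
    def test_moore_degree_eight(self):
        adj = build_topology("moore", 25)
        assert all(len(set(v)) == 8 for v in adj.values())

    def test_von_neumann_degree_four(self):
        adj = build_topology("von_neumann", 16)
        assert all(len(set(v)) == 4 for v in adj.values())

    def test_pairwise_disjoint_pairs(self):
        adj = build_topology("pairwise", 10)
        assert all(len(v) == 1 for v in adj.values())
        # symmetric matching covering everyone exactly once
        assert all(adj[adj[i][0]][0] == i for i in adj)
        assert len({frozenset((i, adj[i][0])) for i in adj}) == 5

    def test_symmetry_of_lattice_adjacency(self):
        adj = build_topology("moore", 16)
        for i, nbrs in adj.items():
            for j in nbrs:
                assert i in adj[j]

    @pytest.mark.parametrize(
        "kind, n", [("pairwise", 7), ("moore", 24), ("von_neumann", 10)]
    )
    def test_invalid_sizes_rejected(self, kind, n):
        with pytest.raises(ValueError):
            build_topology(kind, n)


class TestGenerateCohort:
    def test_same_seed_byte_identical_records(self, tmp_path, small_cohort):
        data2 = generate_cohort(small_cohort.config)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_records(small_cohort.records, p1)
        write_records(data2.records, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_record_count_and_context_schema(self, small_cohort):
        cfg = small_cohort.config
        df = records_to_frame(small_cohort.records)
        assert len(df) == cfg.n_participants * cfg.n_rounds
        assert df.loc[df["round"] == 1, "context"].isna().all()
        assert df.loc[df["round"] > 1, "context"].notna().all()

    def test_ground_truth_covers_everyone(self, small_cohort):
        gt = small_cohort.ground_truth
        pids = {r.participant_id for r in small_cohort.records}
        assert set(gt["participant_id"]) == pids
        assert set(gt["archetype"]) <= set(DEFAULT_ARCHETYPES)

    def test_pure_cooperators_against_defect_context_hit_90(self):
        """ALL_C agents confronted with injected all-defect contexts score 90
        degrees on the strong pairwise matrix."""
        from socialdrift.data import RoundRecord
        from socialdrift.ra import ra_angle

        from socialdrift.cohort import Archetype

        spec = TreatmentSpec("PIPD_c", "pairwise", "fixed", PIPD_MATRIX)
        strong_c = Archetype(
            name="ALL_C", p_coop_first_round=1.0,
            v_mean=4.0, v_sd=0.1, a_mean=1.5, a_sd=0.1, z_mean=0.6,
        )
        config = CohortConfig(
            treatment=spec, mixture={"ALL_C": 1.0}, n_participants=6, n_rounds=21,
            seed=3, archetypes={"ALL_C": strong_c},
        )
        data = generate_cohort(config)
        # replay each cooperator's actions against an all-defecting partner
        checked = 0
        for pid, recs in records_by_pid(data.records).items():
            forced = [
                RoundRecord(pid, "PIPD_c", r.round, r.action, r.rt, 1,
                            None if r.round == 1 else 0)
                for r in recs
            ]
            if all(r.action == "C" for r in forced if r.context is not None):
                assert ra_angle(forced, PIPD_MATRIX).angle_deg == pytest.approx(90.0)
                checked += 1
        assert checked >= 3  # strong drift makes near-sure cooperators

    def test_reciprocator_cohort_concentrates_near_45(self):
        spec = TreatmentSpec("PIPD_r", "pairwise", "fixed", PIPD_MATRIX)
        config = CohortConfig(
            treatment=spec, mixture={"CONDITIONAL": 1.0}, n_participants=30,
            n_rounds=21, seed=4,
        )
        data = generate_cohort(config)
        table = cohort_ra(data.records, spec)
        angles = table.loc[table["defined"], "ra_angle_deg"]
        assert abs(angles.median() - 45.0) < 10.0

    def test_default_experiment_configs_schema(self):
        cfgs = default_experiment_configs()
        assert set(cfgs) == {"PIPD_f", "PIPD_s", "mNIPD_f", "mNIPD_s", "vnNIPD_i", "vnNIPD_o"}
        assert cfgs["PIPD_f"].treatment.topology == "pairwise"
        assert cfgs["PIPD_f"].treatment.payoff_matrix.T == 4
        assert cfgs["mNIPD_f"].treatment.payoff_matrix.P == 0  # the weak matrix
        assert cfgs["mNIPD_f"].n_participants == 169
        assert cfgs["vnNIPD_i"].treatment.n_coplayers == 4
        for c in cfgs.values():
            assert abs(sum(c.mixture.values()) - 1.0) < 1e-9


def records_by_pid(records):
    out = {}
    for r in records:
        out.setdefault(r.participant_id, []).append(r)
    return out


class TestEndToEndRecovery:
    """Fits on generated data recover the archetype structure."""

    @pytest.fixture(scope="class")
    def fitted(self):
        spec = TreatmentSpec("PIPD_e", "pairwise", "shuffled", PIPD_MATRIX, n_rounds=41)
        config = CohortConfig(
            treatment=spec,
            mixture={"ALL_C": 0.3, "ALL_D": 0.3, "CONDITIONAL": 0.4},
            n_participants=60,
            n_rounds=41,
            seed=17,
        )
        data = generate_cohort(config)
        table, _ = build_cohort_table(data.records, spec, seed=17)
        return table.merge(data.ground_truth, on="participant_id")

    def test_archetype_mean_drift_recovered(self, fitted):
        by = fitted.groupby("archetype")["v"].mean()
        assert by["ALL_C"] > 0.5
        assert by["ALL_D"] < -0.5
        assert abs(by["CONDITIONAL"]) < 0.5

    def test_conditional_fitted_drift_smaller_in_magnitude(self, fitted):
        """One-sided rank comparison: conditional agents' |v| is stochastically
        smaller than unconditional agents' |v|."""
        from scipy.stats import mannwhitneyu

        cond = fitted.loc[fitted["archetype"] == "CONDITIONAL", "v"].abs()
        uncond = fitted.loc[fitted["archetype"] != "CONDITIONAL", "v"].abs()
        assert mannwhitneyu(cond, uncond, alternative="less").pvalue < 0.01

    def test_true_parameters_tracked_by_fits(self, fitted):
        rho_a = spearman(fitted["true_a"], fitted["a"]).rho
        rho_v = spearman(fitted["true_v_base"], fitted["v"]).rho
        assert rho_a > 0.5
        assert rho_v > 0.5
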
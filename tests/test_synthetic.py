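import numpy as np
import pytest

from mutualnet.metrics import barber_q, h2prime, modularity
from mutualnet.synthetic import (
    STUDY_TRAIT_EFFECTS,
    SyntheticConfig,
    fai_from_count,
    generate,
    generate_suite,
)


class TestConstruction:
    def test_study_scale_defaults(self):
        data = generate(SyntheticConfig(seed=1))
        assert data.matrix.n_plants == 14
        assert data.matrix.n_birds == 18
        assert data.matrix.m == 4446
        assert (data.matrix.row_totals() > 0).all()
        assert (data.matrix.col_totals() > 0).all()

    def test_records_sum_to_matrix(self):
        data = generate(SyntheticConfig(m=500, seed=3))
        assert sum(r.count for r in data.records) == 500
        assert {r.season for r in data.records} <= {"rainy", "dry"}

    def test_trait_tables_are_valid(self):
        from mutualnet.io import validate_trait_table

        data = generate(SyntheticConfig(seed=2))
        validate_trait_table(data.bird_traits, "bird")
        validate_trait_table(data.plant_traits, "plant")

    def test_same_seed_is_byte_identical(self):
        a = generate(SyntheticConfig(seed=7))
        b = generate(SyntheticConfig(seed=7))
        assert np.array_equal(a.matrix.w, b.matrix.w)
        assert a.records == b.records
        assert a.bird_traits.equals(b.bird_traits)
        assert np.array_equal(a.truth.lambda_birds, b.truth.lambda_birds)

    def test_different_seeds_differ(self):
        a = generate(SyntheticConfig(seed=1))
        b = generate(SyntheticConfig(seed=2))
        assert not np.array_equal(a.matrix.w, b.matrix.w)


class TestFai:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, 0), (1, 1), (10, 1), (11, 2), (100, 2), (101, 3), (1000, 3), (5000, 4), (10001, 5)],
    )
    def test_ordinal_boundaries(self, count, expected):
        assert fai_from_count(count) == expected


class TestSpecializationLimits:
    def test_weak_matching_gives_generalized_webs(self):
        values = [
            h2prime(generate(SyntheticConfig(match_sd=1e6, seed=s)).matrix).H2prime
            for s in range(50)
        ]
        assert all(v < 0.2 for v in values)

    def test_strong_matching_gives_specialized_webs(self):
        values = [
            h2prime(generate(SyntheticConfig(match_sd=0.2, seed=s)).matrix).H2prime
            for s in range(50)
        ]
        assert all(v > 0.4 for v in values)


class TestPlantedModules:
    def test_block_boost_raises_modularity(self):
        q0, q3 = [], []
        for s in range(10):
            d0 = generate(SyntheticConfig(m=800, match_sd=1e6, block_boost=0.0, seed=s))
            d3 = generate(SyntheticConfig(m=800, match_sd=1e6, block_boost=3.0, seed=s))
            q0.append(modularity(d0.matrix, n_restarts=5, seed=s).Q)
            q3.append(modularity(d3.matrix, n_restarts=5, seed=s).Q)
        assert np.mean(q3) > np.mean(q0)

    def test_planted_partition_is_near_optimal(self):
        """Optimizer sanity anchor: the true block labels score within 10%."""
        for s in range(8):
            data = generate(SyntheticConfig(match_sd=1e6, block_boost=3.0, seed=s))
            q_opt = modularity(data.matrix, n_restarts=5, seed=s).Q
            q_planted = barber_q(
                data.matrix, data.truth.block_plants, data.truth.block_birds
            )
            assert q_planted >= 0.9 * q_opt


class TestSeasonTagging:
    def test_rainy_share_close_to_configured(self):
        data = generate(SyntheticConfig(rainy_fraction=0.52, seed=4))
        rainy_m = sum(r.count for r in data.records if r.season == "rainy")
        share = rainy_m / data.matrix.m
        # binomial error at m=4446 is ~0.0075; allow 4 sd
        assert abs(share - 0.52) < 0.03


class TestTraitCoupling:
    def test_mass_couples_to_roles_with_study_preset(self):
        from mutualnet.metrics import species_metrics

        corr_deg, corr_dp = [], []
        for s in range(6):
            data = generate(
                SyntheticConfig(
                    n_birds=40, n_plants=20, m=8000, match_sd=0.4,
                    trait_effects=STUDY_TRAIT_EFFECTS, seed=s,
                )
            )
            sp = species_metrics(data.matrix)
            birds = sp[sp["role"] == "bird"].join(data.bird_traits)
            corr_deg.append(np.corrcoef(np.log(birds["body_mass"]), birds["degree"])[0, 1])
            corr_dp.append(np.corrcoef(np.log(birds["body_mass"]), birds["dprime"])[0, 1])
        assert np.mean(corr_deg) < -0.3
        assert np.mean(corr_dp) > 0.3


class TestSuite:
    def test_grid_is_deterministic_and_valid(self):
        suite = generate_suite(
            match_sds=(0.3, 2.0), block_boosts=(0.0, 3.0), n_seeds=2, m=400, seed=9
        )
        again = generate_suite(
            match_sds=(0.3, 2.0), block_boosts=(0.0, 3.0), n_seeds=2, m=400, seed=9
        )
        assert len(suite) == 8
        for a, b in zip(suite, again):
            assert np.array_equal(a.matrix.w, b.matrix.w)
            assert a.matrix.m == 400
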
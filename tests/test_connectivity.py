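import numpy as np
import pandas as pd
import pytest

from sigconnect.expression import L2FCProfile, ProfileDatabase
from sigconnect.connectivity import (
    ALGORITHMS,
    SCORE_BOUNDS,
    rank_references,
    score_extreme,
    score_gtes,
    score_pair,
    score_sji,
    weighted_ks_es,
)
from sigconnect.signatures import (
    QuerySignature,
    RestrictedProfile,
    _ranked_genes,
    make_query_signature,
    restrict_reference,
)


def brute_force_es(gene_set, ranking: pd.Series, weight_p: float) -> float:
    """Oracle: build the full running sum explicitly and take its extremum."""
    genes = list(ranking.index)
    values = ranking.to_numpy(dtype=float)
    member = np.array([g in gene_set for g in genes])
    weights = np.where(member, np.abs(values) ** weight_p, 0.0)
    if weights.sum() == 0:
        weights = member.astype(float)
    n_hit = member.sum()
    steps = np.where(member, weights / weights.sum(), -1.0 / (len(genes) - n_hit))
    running = np.cumsum(steps)
    max_dev, min_dev = running.max(), min(running.min(), 0.0)
    # exactly balanced deviations score 0 (implementation convention)
    if abs(max_dev + min_dev) <= 1e-12:
        return 0.0 if max_dev > 0 else float(max_dev)
    return float(max_dev) if max_dev > -min_dev else float(min_dev)


def random_ranking(rng, n=20):
    values = np.sort(rng.standard_normal(n))[::-1]
    return pd.Series(values, index=[f"g{i:03d}" for i in range(n)])


def make_restricted(up, down, values: pd.Series) -> RestrictedProfile:
    ranked = values.sort_values(ascending=False)
    return RestrictedProfile(up=set(up), down=set(down),
                             values=ranked[ranked.index.isin(set(up) | set(down))],
                             full_ranking=ranked, nr=len(up), reference_id="ref")


def make_query(up, down, values: pd.Series) -> QuerySignature:
    return QuerySignature(up=list(up), down=list(down),
                          values=values, nq=len(up), query_id="q")


class TestWeightedKS:
    def test_single_top_gene_es_one(self):
        ranking = random_ranking(np.random.default_rng(0), 10)
        assert weighted_ks_es({ranking.index[0]}, ranking, 0) == pytest.approx(1.0)

    def test_single_bottom_gene(self):
        # N=4, set = {rank 4}: running sum -1/3, -2/3, -1, 0 -> extremum -1
        ranking = pd.Series([3.0, 2.0, 1.0, -1.0], index=list("abcd"))
        assert weighted_ks_es({"d"}, ranking, 0) == pytest.approx(-1.0)
        assert brute_force_es({"d"}, ranking, 0) == pytest.approx(-1.0)

    @pytest.mark.parametrize("weight_p", [0.0, 1.0])
    def test_matches_oracle(self, rng, weight_p):
        for _ in range(50):
            ranking = random_ranking(rng, 20)
            size = int(rng.integers(1, 19))
            gene_set = set(rng.choice(ranking.index, size=size, replace=False))
            assert weighted_ks_es(gene_set, ranking, weight_p) == pytest.approx(
                brute_force_es(gene_set, ranking, weight_p), abs=1e-12
            )

    def test_empty_intersection_errors(self):
        ranking = random_ranking(np.random.default_rng(1), 5)
        with pytest.raises(ValueError, match="intersect"):
            weighted_ks_es({"absent"}, ranking, 1)

    def test_full_universe_errors(self):
        ranking = random_ranking(np.random.default_rng(1), 5)
        with pytest.raises(ValueError, match="entire"):
            weighted_ks_es(set(ranking.index), ranking, 1)


class TestSji:
    def test_perfect_match(self):
        values = pd.Series({"a": 2.0, "b": 1.0, "c": -1.0, "d": -2.0})
        q = make_query(["a"], ["d"], values)
        r = make_restricted(["a"], ["d"], values)
        assert score_sji(q, r) == pytest.approx(1.0)

    def test_swapped_directions(self):
        values = pd.Series({"a": 2.0, "d": -2.0})
        q = make_query(["a"], ["d"], values)
        r = make_restricted(["d"], ["a"], pd.Series({"d": 2.0, "a": -2.0}))
        assert score_sji(q, r) == pytest.approx(-1.0)

    def test_no_overlap(self):
        values = pd.Series({"a": 2.0, "d": -2.0, "x": 1.0, "y": -1.0})
        q = make_query(["a"], ["d"], values)
        r = make_restricted(["x"], ["y"], values)
        assert score_sji(q, r) == pytest.approx(0.0)


class TestExtremeScores:
    def _pair(self, rng, negate=False):
        n = 40
        values = pd.Series(rng.standard_normal(n), index=[f"g{i:02d}" for i in range(n)])
        profile = L2FCProfile(treatment_id="p", values=values)
        q = make_query_signature(profile, 5)
        ref_values = -values if negate else values
        r = restrict_reference(L2FCProfile(treatment_id="r", values=ref_values), 20)
        return q, r

    def test_self_match_is_one(self, rng):
        q, r = self._pair(rng)
        for flavor in ("xc", "xcp", "xcs"):
            assert score_extreme(q, r, flavor) == pytest.approx(1.0)

    def test_negated_reference_is_minus_one(self, rng):
        q, r = self._pair(rng, negate=True)
        for flavor in ("xc", "xcp", "xcs"):
            assert score_extreme(q, r, flavor) == pytest.approx(-1.0)

    def test_orthogonal_vectors_zero_cosine(self):
        values = pd.Series({"a": 1.0, "b": -1.0, "c": 5.0, "d": -5.0})
        q = make_query(["a"], ["b"], pd.Series({"a": 1.0, "b": -1.0}))
        ref = pd.Series({"a": 1.0, "b": 1.0, "c": 5.0, "d": -5.0})
        r = make_restricted({"a", "b", "c"}, {"d"}, ref)
        # y = (1, 1) vs x = (1, -1): orthogonal
        assert score_extreme(q, r, "xc", min_overlap=2) == pytest.approx(0.0)

    def test_insufficient_overlap_is_nan(self, rng):
        q, _ = self._pair(rng)
        outside = pd.Series({"z1": 1.0, "z2": 0.5, "z3": -1.0, "z4": -0.5})
        r = make_restricted({"z1", "z2"}, {"z3", "z4"}, outside)
        assert np.isnan(score_extreme(q, r, "xcp"))

    def test_unknown_flavor(self, rng):
        q, r = self._pair(rng)
        with pytest.raises(ValueError):
            score_extreme(q, r, "cosine")


class TestGtes:
    def test_strong_self_match_exceeds_three(self, rng):
        n = 1000
        values = pd.Series(rng.standard_normal(n) * 2,
                           index=[f"g{i:04d}" for i in range(n)])
        profile = L2FCProfile(treatment_id="p", values=values)
        q = make_query_signature(profile, 100)
        r = restrict_reference(profile, 300)
        assert score_gtes(q, _ranked_genes(profile), r) > 3.0

    def test_antisymmetric_under_reference_negation(self, rng):
        n = 200
        q_values = pd.Series(rng.standard_normal(n), index=[f"g{i:03d}" for i in range(n)])
        r_values = pd.Series(rng.standard_normal(n), index=q_values.index)
        profile = L2FCProfile(treatment_id="p", values=q_values)
        q = make_query_signature(profile, 20)
        q_full = _ranked_genes(profile)
        r = restrict_reference(L2FCProfile(treatment_id="r", values=r_values), 50)
        r_neg = restrict_reference(L2FCProfile(treatment_id="r", values=-r_values), 50)
        assert score_gtes(q, q_full, r_neg) == pytest.approx(
            -score_gtes(q, q_full, r), abs=1e-12
        )


class TestScoreInvariances:
    def test_unrelated_gene_perturbation_no_effect(self, rng):
        n = 120
        values = pd.Series(rng.standard_normal(n), index=[f"g{i:03d}" for i in range(n)])
        profile = L2FCProfile(treatment_id="p", values=values)
        q = make_query_signature(profile, 10)
        ref = pd.Series(rng.standard_normal(n), index=values.index)
        r = restrict_reference(L2FCProfile(treatment_id="r", values=ref), 30)
        touched = set(q.genes) | r.up | r.down
        untouched = [g for g in values.index if g not in touched]
        perturbed = ref.copy()
        # shrink untouched values toward zero: stays outside the extremes
        perturbed[untouched] = perturbed[untouched] * 0.5
        r2 = restrict_reference(L2FCProfile(treatment_id="r", values=perturbed), 30)
        assert r2.up == r.up and r2.down == r.down
        for flavor in ("sji", "xc", "xcp", "xcs"):
            before = score_pair(q, _ranked_genes(profile), r, [flavor])[flavor]
            after = score_pair(q, _ranked_genes(profile), r2, [flavor])[flavor]
            assert after == pytest.approx(before, abs=1e-12)

    def test_bounds_on_random_pairs(self, rng):
        for _ in range(30):
            n = 80
            values = pd.Series(rng.standard_normal(n), index=[f"g{i:03d}" for i in range(n)])
            ref = pd.Series(rng.standard_normal(n), index=values.index)
            profile = L2FCProfile(treatment_id="p", values=values)
            q = make_query_signature(profile, 8)
            r = restrict_reference(L2FCProfile(treatment_id="r", values=ref), 20)
            scores = score_pair(q, _ranked_genes(profile), r, ALGORITHMS)
            for algorithm, value in scores.items():
                low, high = SCORE_BOUNDS[algorithm]
                assert low - 1e-9 <= value <= high + 1e-9


class TestRanking:
    def _db(self, rng, n_profiles=6, n=300):
        genes = [f"g{i:03d}" for i in range(n)]
        profiles = [
            L2FCProfile(treatment_id=f"chem{i:02d}-10.00uM-24h-rn-hep-ref",
                        values=pd.Series(rng.standard_normal(n), index=genes))
            for i in range(n_profiles)
        ]
        return ProfileDatabase(profiles=profiles)

    def test_self_profile_ranks_first_every_algorithm(self, rng):
        db = self._db(rng)
        target = db.profiles[3]
        q = make_query_signature(target, 30)
        q_full = _ranked_genes(target)
        for algorithm in ALGORITHMS:
            hits = rank_references(q, q_full, db, nr=60, algorithm=algorithm)
            assert hits.iloc[0]["reference_id"] == target.treatment_id, algorithm

    def test_singleton_db(self, rng):
        db = self._db(rng, n_profiles=1)
        q = make_query_signature(db.profiles[0], 10)
        hits = rank_references(q, _ranked_genes(db.profiles[0]), db, nr=50)
        assert len(hits) == 1 and hits.iloc[0]["rank"] == 1

    def test_nan_scores_rank_last(self, rng):
        db = self._db(rng, n_profiles=3)
        # a reference sharing no genes with the query yields undefined scores
        alien = L2FCProfile(
            treatment_id="alien-10.00uM-24h-rn-hep-ref",
            values=pd.Series(np.random.default_rng(5).standard_normal(50),
                             index=[f"x{i}" for i in range(50)]),
        )
        db = ProfileDatabase(profiles=db.profiles + [alien])
        q = make_query_signature(db.profiles[0], 20)
        hits = rank_references(q, _ranked_genes(db.profiles[0]), db, nr=50,
                               algorithm="xcp")
        assert hits.iloc[-1]["reference_id"] == alien.treatment_id
        assert np.isnan(hits.iloc[-1]["xcp"])
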
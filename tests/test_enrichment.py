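import itertools
import math
from importlib import resources

import numpy as np
import pytest
from scipy.special import comb

from rtomics.enrichment import (
    GmtError,
    PathwaySet,
    joint_pathway,
    ora,
    qea,
    read_gmt,
    write_gmt,
)
from rtomics.tables import CohortMetadata, FeatureTable, half_min_impute, log_autoscale


class TestGmt:
    def test_round_trip(self, tmp_path):
        sets = [PathwaySet("p1", "first", frozenset({"a", "b"})),
                PathwaySet("p2", "second", frozenset({"c"}))]
        path = tmp_path / "t.gmt"
        write_gmt(sets, path)
        back = read_gmt(path)
        assert [(s.pathway_id, s.members) for s in back] == \
               [(s.pathway_id, s.members) for s in sets]

    def test_short_line_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("p1\tdesc\ta\np2\tonly-two-fields\n")
        with pytest.raises(GmtError, match=":2:"):
            read_gmt(path)

    def test_duplicate_pathway_name_rejected(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("p1\td\ta\np1\td\tb\n")
        with pytest.raises(GmtError, match="duplicate"):
            read_gmt(path)

    def test_duplicate_members_deduplicated(self, tmp_path):
        path = tmp_path / "m.gmt"
        path.write_text("p1\td\ta\ta\tb\n")
        assert read_gmt(path)[0].members == frozenset({"a", "b"})

    def test_bundled_toy_pathways_parse(self):
        with resources.as_file(resources.files("rtomics.data") / "toy_pathways.gmt") as p:
            sets = read_gmt(p)
        assert len(sets) == 8
        assert all(len(s.members) == 15 for s in sets)


def _exhaustive_ora_p(universe_n, members, hits):
    """P(overlap >= observed) by enumerating all draws of |hits| from the universe."""
    universe = list(range(universe_n))
    k_obs = len(set(hits) & set(members))
    total = hit = 0
    for draw in itertools.combinations(universe, len(hits)):
        total += 1
        if len(set(draw) & set(members)) >= k_obs:
            hit += 1
    return hit / total


class TestOra:
    def test_single_table_hand_example(self):
        universe = [f"g{i}" for i in range(20)]
        pw = PathwaySet("p", "p", frozenset(universe[:5]))
        rec = ora(set(universe[:5]), universe, [pw])[0]
        assert rec.p_value == pytest.approx(1 / comb(20, 5))
        assert rec.n_hits == 5
        assert rec.enrichment_ratio == pytest.approx(4.0)

    def test_empty_hits_give_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        rec = ora(set(), universe, [PathwaySet("p", "p", frozenset(universe[:4]))])[0]
        assert rec.p_value == 1.0

    def test_matches_exhaustive_enumeration_small_universe(self):
        rng = np.random.default_rng(13)
        universe = [f"g{i}" for i in range(12)]
        for _ in range(10):
            m = rng.integers(2, 7)
            h = rng.integers(1, 7)
            members = set(rng.choice(universe, size=m, replace=False))
            hits = set(rng.choice(universe, size=h, replace=False))
            rec = ora(hits, universe, [PathwaySet("p", "p", frozenset(members))])[0]
            expected = _exhaustive_ora_p(
                12, [universe.index(x) for x in members], [universe.index(x) for x in hits])
            assert rec.p_value == pytest.approx(expected, rel=1e-9)

    def test_hits_must_be_in_universe(self):
        with pytest.raises(ValueError, match="universe"):
            ora({"x"}, {"a", "b"}, [])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(40)]
        pws = [PathwaySet(f"p{i}", "", frozenset(rng.choice(universe, 8, replace=False)))
               for i in range(6)]
        hits = set(rng.choice(universe, 10, replace=False))
        for r in ora(hits, universe, pws):
            assert r.q_value >= r.p_value - 1e-15


@pytest.fixture(scope="module")
def qea_cohort():
    from rtomics import SyntheticConfig, generate_cohort
    cfg = SyntheticConfig(n_per_group=12, n_protein_features=5, n_metabolite_features=60,
                          frac_differential=0.25, effect_size=2.0,
                          frac_exclusive=0.0, missing_rate=0.0, seed=77)
    _, met, meta, truth = generate_cohort(cfg)
    table = log_autoscale(half_min_impute(met))
    planted = sorted(f for f in truth.differential_feature_ids if f.startswith("MET"))
    return table, meta, planted


class TestQea:
    def test_deterministic_given_seed(self, qea_cohort):
        table, meta, planted = qea_cohort
        pws = [PathwaySet("pw", "", frozenset(planted[:5]))]
        p1 = qea(table, meta, pws, n_permutations=300, seed=9)[0].p_value
        p2 = qea(table, meta, pws, n_permutations=300, seed=9)[0].p_value
        assert p1 == p2

    def test_scale_invariant(self, qea_cohort):
        table, meta, planted = qea_cohort
        pws = [PathwaySet("pw", "", frozenset(planted[:5]))]
        scaled = FeatureTable(table.values * 37.0, "metabolite", transformed=True)
        assert qea(table, meta, pws, 300, seed=1)[0].p_value == \
               qea(scaled, meta, pws, 300, seed=1)[0].p_value

    def test_planted_pathway_significant(self, qea_cohort):
        table, meta, planted = qea_cohort
        nulls = [f for f in table.feature_ids if f not in planted]
        pws = [PathwaySet("planted", "", frozenset(planted[:5]))] + [
            PathwaySet(f"null{i}", "", frozenset(nulls[i * 5:(i + 1) * 5]))
            for i in range(5)]
        recs = {r.pathway_id: r for r in qea(table, meta, pws, 1000, seed=2)}
        assert recs["planted"].q_value < 0.05

    def test_unmeasured_pathway_skipped(self, qea_cohort):
        table, meta, _ = qea_cohort
        pws = [PathwaySet("ghost", "", frozenset({"NOT_A_FEATURE"}))]
        assert qea(table, meta, pws, 300, seed=0) == []


class TestJointPathway:
    def test_reduces_to_single_layer_ora(self):
        genes = [f"gene:{i}" for i in range(20)]
        pw = PathwaySet("p", "", frozenset(genes[:5]))
        joint = joint_pathway(set(genes[:5]), set(), genes, set(), [pw])[0]
        single = ora(set(genes[:5]), genes, [pw])[0]
        assert joint.p_value == pytest.approx(single.p_value)
        assert joint.impact == pytest.approx(single.enrichment_ratio)

    def test_pooled_membership_hand_example(self):
        genes = [f"gene:{i}" for i in range(80)]
        mets = [f"met:{i}" for i in range(20)]
        pw = PathwaySet("p", "", frozenset(genes[:10] + mets[:5]))
        rec = joint_pathway(set(genes[:10]), set(mets[:5]), genes, mets, [pw])[0]
        # all 15 members hit among 15 hits from universe 100
        assert rec.n_hits == 15
        assert rec.n_hits_gene == 10 and rec.n_hits_metabolite == 5
        assert rec.p_value == pytest.approx(1 / comb(100, 15), rel=1e-6)

    def test_identifier_collision_rejected(self):
        with pytest.raises(ValueError, match="collision"):
            joint_pathway(set(), set(), {"x"}, {"x"}, [])

    def test_node_weight_hook_changes_impact(self):
        genes = [f"gene:{i}" for i in range(10)]
        pw = PathwaySet("p", "", frozenset(genes[:4]))
        weights = {g: (2.0 if g == "gene:0" else 1.0) for g in genes}
        rec = joint_pathway({"gene:0"}, set(), genes, set(), [pw], node_weights=weights)[0]
        assert rec.impact == pytest.approx(2.0 / 5.0)
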
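import itertools

import numpy as np
import pandas as pd
import pytest

from phyllocom.community import (ConfoundedTermsError, DistanceMatrix,
                                 braycurtis, permanova)
from phyllocom.datamodel import CountTable

from conftest import make_meta


def table_of(rows, ids=None):
    rows = np.asarray(rows)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    return CountTable(
        pd.DataFrame(rows, index=ids, columns=[f"o{j}" for j in range(rows.shape[1])])
    )


class TestBrayCurtis:
    def test_identical_rows(self):
        d = braycurtis(table_of([[2, 2, 0], [2, 2, 0]]))
        assert d.values[0, 1] == 0.0

    def test_disjoint_rows(self):
        d = braycurtis(table_of([[5, 0], [0, 5]]))
        assert d.values[0, 1] == 1.0

    def test_worked_example(self):
        d = braycurtis(table_of([[2, 2, 0], [0, 2, 2]]))
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            braycurtis(table_of([[1, 1], [0, 0]]))


class TestPermanova:
    def _two_group_distance(self):
        # two groups of duplicated samples: within 0, between 1
        rows = [[10, 0]] * 4 + [[0, 10]] * 4
        return braycurtis(table_of(rows))

    def test_perfect_separation(self):
        d = self._two_group_distance()
        meta = make_meta(d.sample_ids, organ=["leaf"] * 4 + ["flower"] * 4)
        res = permanova(d, meta, ["organ"], n_permutations=99, rng_seed=0)
        row = res.table.set_index("term")
        assert row.loc["organ", "r2"] == pytest.approx(1.0, abs=1e-9)
        assert row.loc["Residual", "ss"] == pytest.approx(0.0, abs=1e-9)

    def test_r2_sums_to_one_and_gower_identity(self):
        rng = np.random.default_rng(1)
        d = braycurtis(table_of(rng.integers(0, 30, (12, 8))))
        meta = make_meta(d.sample_ids,
                         organ=list(rng.choice(["leaf", "flower"], 12)),
                         host=list(rng.choice(["a", "b", "c"], 12)))
        res = permanova(d, meta, ["host", "organ"], n_permutations=49, rng_seed=2)
        body = res.table[res.table["term"] != "Total"]
        assert body["r2"].sum() == pytest.approx(1.0)
        n = len(d.sample_ids)
        assert res.total_ss == pytest.approx(
            (d.values[np.triu_indices(n, 1)] ** 2).sum() / n
        )

    def test_term_order_changes_sequential_ss_not_total(self):
        rng = np.random.default_rng(3)
        # correlated factors so sequential SS is genuinely order-dependent
        organ = list(rng.choice(["leaf", "flower"], 16))
        host = [
            o if rng.random() < 0.3 else h
            for o, h in zip(organ, rng.choice(["a", "b"], 16))
        ]
        d = braycurtis(table_of(rng.integers(0, 30, (16, 10))))
        meta = make_meta(d.sample_ids, organ=organ, host=host)
        r1 = permanova(d, meta, ["host", "organ"], n_permutations=19, rng_seed=0)
        r2 = permanova(d, meta, ["organ", "host"], n_permutations=19, rng_seed=0)
        assert r1.total_ss == pytest.approx(r2.total_ss)
        ss1 = r1.table.set_index("term").loc["host", "ss"]
        ss2 = r2.table.set_index("term").loc["host", "ss"]
        assert ss1 != pytest.approx(ss2)

    def test_confounded_terms_error(self):
        d = self._two_group_distance()
        organ = ["leaf"] * 4 + ["flower"] * 4
        meta = make_meta(d.sample_ids, organ=organ, host=organ)
        with pytest.raises(ConfoundedTermsError, match="host"):
            permanova(d, meta, ["organ", "host"], n_permutations=9)

    def test_exhaustive_enumeration_oracle_n4(self):
        """Sampled permutation p matches brute-force enumeration at n=4."""
        rng = np.random.default_rng(5)
        table = table_of(rng.integers(1, 30, (4, 6)))
        d = braycurtis(table)
        labels = ["leaf", "leaf", "flower", "flower"]
        meta = make_meta(d.sample_ids, organ=labels)

        def f_of(perm):
            dd = DistanceMatrix(d.sample_ids, d.values[np.ix_(perm, perm)])
            res = permanova(dd, meta, ["organ"], n_permutations=1, rng_seed=0)
            return res.table.set_index("term").loc["organ", "pseudo_F"]

        f_obs = f_of(list(range(4)))
        fs = [f_of(list(p)) for p in itertools.permutations(range(4))]
        exact = sum(f >= f_obs - 1e-12 for f in fs) / len(fs)
        res = permanova(d, meta, ["organ"], n_permutations=20_000, rng_seed=7)
        p_sampled = res.table.set_index("term").loc["organ", "pvalue"]
        assert abs(p_sampled - exact) < 0.02

    def test_single_factor_matches_skbio_and_anova(self):
        """Pseudo-F equals scikit-bio's PERMANOVA and, on Euclidean
        distances, the classical one-way ANOVA F on the coordinates."""
        skbio_distance = pytest.importorskip("skbio").DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(11)
        coords = rng.normal(size=(15, 1))
        labels = list(rng.choice(["a", "b", "c"], 15))
        dvals = np.abs(coords - coords.T)
        ids = [f"s{i}" for i in range(15)]
        d = DistanceMatrix(ids, dvals)
        meta = make_meta(ids, host=labels)
        res = permanova(d, meta, ["host"], n_permutations=99, rng_seed=0)
        f_mine = res.table.set_index("term").loc["host", "pseudo_F"]

        sk = skbio_permanova(skbio_distance(dvals, ids), grouping=labels,
                             permutations=9)
        assert f_mine == pytest.approx(sk["test statistic"], rel=1e-10)

        import scipy.stats as ss
        groups = [coords[np.array(labels) == g, 0] for g in ("a", "b", "c")]
        f_anova = ss.f_oneway(*groups).statistic
        assert f_mine == pytest.approx(f_anova, rel=1e-8)

    def test_strata_restrict_permutations(self):
        rng = np.random.default_rng(13)
        d = braycurtis(table_of(rng.integers(0, 30, (12, 8))))
        meta = make_meta(d.sample_ids,
                         organ=list(rng.choice(["leaf", "flower"], 12)),
                         time_point=[1] * 6 + [2] * 6)
        res = permanova(d, meta, ["organ"], n_permutations=49, rng_seed=1,
                        strata="time_point")
        p = res.table.set_index("term").loc["organ", "pvalue"]
        assert 1 / 50 <= p <= 1.0
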
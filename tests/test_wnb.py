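"""Attribute-weighted naive Bayes: weights, posteriors, tie-breaks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofuse import wnb


def oracle_posterior(rows, labels, query, lam=1.0, weighted=True):
    """Enumeration oracle: evaluates the weighted posterior directly from
    raw counts, independent of the fitted model's internals."""
    classes = sorted(set(labels))
    n, m = len(rows), len(rows[0])
    scores = {}
    for c in classes:
        nc = sum(1 for lab in labels if lab == c)
        s = nc / n
        for j, v in enumerate(query):
            values = sorted({r[j] for r in rows}, key=repr)
            nvc = sum(1 for r, lab in zip(rows, labels)
                      if r[j] == v and lab == c)
            nv = sum(1 for r in rows if r[j] == v)
            if v in values:
                p = (nvc + lam) / (nc + lam * len(values))
            else:
                p = lam / (nc + lam * (len(values) + 1))
            w = 1.0 if (nv == 0 or not weighted) else (m + nvc / nv) / m
            s *= p * w
        scores[c] = s
    z = sum(scores.values())
    return {c: s / z for c, s in scores.items()}


def random_table(rng, n_rows=None, n_attrs=None):
    n_rows = n_rows or int(rng.integers(4, 13))
    n_attrs = n_attrs or int(rng.integers(2, 4))
    values = ["ASD", "TD", "unsure"]
    while True:
        rows = [tuple(rng.choice(values, size=n_attrs)) for _ in range(n_rows)]
        labels = [str(lab) for lab in rng.choice(["ASD", "TD"], size=n_rows)]
        if len(set(labels)) == 2:
            return rows, labels


WORKED_ROWS = [("ASD",), ("ASD",), ("ASD",), ("TD",)]
WORKED_LABELS = ["ASD", "ASD", "TD", "TD"]


class TestWeights:
    def test_worked_example_weight_four_thirds(self):
        # 2 attributes, value ASD seen 3x (2x with class ASD):
        # W = (2 + 2/3) / 2 = 4/3
        rows = [(d, d) for (d,) in WORKED_ROWS]
        model = wnb.fit(rows, WORKED_LABELS)
        assert model.weights[0]["ASD"]["ASD"] == pytest.approx(4 / 3)

    def test_value_never_seen_with_class_gives_weight_one(self):
        rows = [("a", "x"), ("a", "x"), ("b", "x"), ("b", "x")]
        labels = ["ASD", "ASD", "TD", "TD"]
        model = wnb.fit(rows, labels)
        # value "a" never occurs with class TD
        assert model.weights[0]["a"]["TD"] == 1.0

    def test_value_exclusive_to_class_hits_upper_bound(self):
        rows = [("a", "x"), ("a", "x"), ("b", "x"), ("b", "x")]
        labels = ["ASD", "ASD", "TD", "TD"]
        model = wnb.fit(rows, labels)
        assert model.weights[0]["a"]["ASD"] == pytest.approx((2 + 1) / 2)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10 ** 6))
    def test_weight_bounds(self, seed):
        rng = np.random.default_rng(seed)
        rows, labels = random_table(rng)
        model = wnb.fit(rows, labels)
        hi = (model.n_attributes + 1) / model.n_attributes
        for table in model.weights:
            for per_class in table.values():
                for w in per_class.values():
                    assert 1.0 <= w <= hi + 1e-12


class TestPosterior:
    @pytest.mark.parametrize("trial", range(25))
    def test_matches_enumeration_oracle(self, trial):
        rng = np.random.default_rng(trial)
        rows, labels = random_table(rng)
        model = wnb.fit(rows, labels)
        for _ in range(4):
            query = rows[int(rng.integers(len(rows)))]
            got = model.posterior(query)
            want = oracle_posterior(rows, labels, query)
            for c in got:
                assert got[c] == pytest.approx(want[c], abs=1e-12)

    def test_worked_four_row_example_against_oracle(self):
        model = wnb.fit(WORKED_ROWS, WORKED_LABELS)
        got = model.posterior(("ASD",))
        want = oracle_posterior(WORKED_ROWS, WORKED_LABELS, ("ASD",))
        assert got["ASD"] == pytest.approx(want["ASD"], abs=1e-15)

    def test_symmetric_table_symmetric_query(self):
        rows = [("a", "b"), ("b", "a"), ("a", "b"), ("b", "a")]
        labels = ["ASD", "TD", "ASD", "TD"]
        model = wnb.fit(rows, labels)
        # a query equally compatible with both classes by symmetry
        post = model.posterior(("a", "a"))
        assert post["ASD"] == pytest.approx(0.5)

    def test_posterior_sums_to_one(self, rng):
        rows, labels = random_table(rng)
        model = wnb.fit(rows, labels)
        post = model.posterior(rows[0])
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)

    def test_unseen_value_falls_back_gracefully(self, rng):
        rows, labels = random_table(rng)
        model = wnb.fit(rows, labels)
        query = tuple("never_seen" for _ in rows[0])
        post = model.posterior(query)
        assert sum(post.values()) == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_forcing_unit_weights_reproduces_plain_nb(self, trial):
        rng = np.random.default_rng(500 + trial)
        rows, labels = random_table(rng)
        model = wnb.fit(rows, labels, use_weights=False)
        query = rows[0]
        got = model.posterior(query)
        want = oracle_posterior(rows, labels, query, weighted=False)
        for c in got:
            assert got[c] == pytest.approx(want[c], abs=1e-12)

    def test_attribute_permutation_invariance(self, rng):
        rows, labels = random_table(rng, n_attrs=3)
        perm = [(r[2], r[0], r[1]) for r in rows]
        m1 = wnb.fit(rows, labels)
        m2 = wnb.fit(perm, labels)
        q = rows[1]
        p1 = m1.posterior(q)
        p2 = m2.posterior((q[2], q[0], q[1]))
        assert p1["ASD"] == pytest.approx(p2["ASD"], abs=1e-12)

    def test_duplicating_rows_preserves_weights(self, rng):
        rows, labels = random_table(rng)
        m1 = wnb.fit(rows, labels)
        m2 = wnb.fit(rows * 2, labels * 2)
        assert m1.weights == m2.weights


class TestPredict:
    def test_argmax(self):
        rows = [("a",)] * 3 + [("b",)] * 3
        labels = ["ASD"] * 3 + ["TD"] * 3
        model = wnb.fit(rows, labels)
        assert model.predict(("a",)) == "ASD"
        assert model.predict(("b",)) == "TD"

    def test_exact_tie_equal_priors_canonical_order(self):
        rows = [("a", "b"), ("b", "a"), ("a", "b"), ("b", "a")]
        labels = ["ASD", "TD", "ASD", "TD"]
        model = wnb.fit(rows, labels)
        assert model.predict(("a", "a")) == "ASD"

    def test_tie_broken_by_larger_prior(self):
        # attribute uninformative; imbalanced classes
        rows = [("x",)] * 5
        labels = ["TD", "TD", "TD", "ASD", "ASD"]
        model = wnb.fit(rows, labels)
        assert model.predict(("x",)) == "TD"


class TestValidation:
    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="classes"):
            wnb.fit([("a",), ("b",)], ["ASD", "ASD"])

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            wnb.fit([], [])

    def test_arity_mismatch_errors(self):
        model = wnb.fit([("a", "b"), ("b", "a")], ["ASD", "TD"])
        with pytest.raises(ValueError, match="attributes"):
            model.posterior(("a",))

    def test_json_roundtrip_is_stable(self):
        model = wnb.fit(WORKED_ROWS, WORKED_LABELS)
        assert model.to_json() == wnb.fit(WORKED_ROWS,
                                          WORKED_LABELS).to_json()
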
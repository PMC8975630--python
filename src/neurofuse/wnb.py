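"""Attribute-weighted naive Bayes over categorical subdecisions.

Standard naive Bayes treats every attribute as equally informative.  Here
each conditional probability P(d_m = v | c_i) is multiplied by a
data-derived weighting coefficient

    W(d_m = v | c_i) = [ n(m) + n(d_m = v and c_i) / n(d_m = v) ] / n(m)

where n(m) is the number of attributes (decisions), n(d_m = v) the number
of training rows with value v on attribute m, and n(d_m = v and c_i) the
subset of those with class c_i.  The ratio term is the empirical
P(c_i | d_m = v), so an attribute value strongly associated with a class
gets a coefficient near (n(m)+1)/n(m) while an uninformative or unseen one
stays at 1; every weight lies in [1, (n(m)+1)/n(m)].

The posterior is the weighted product

    score(c_i) = P(c_i) * prod_j P(d_j | c_i) * W(d_j | c_i)

normalised over classes (computed in log space).  Conditionals use Laplace
smoothing; weights use raw counts, since the additive n(m) term already
guards against zeros.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Sequence

__all__ = ["WeightedNaiveBayes", "fit", "posterior", "predict"]

Value = Hashable
Row = Sequence[Value]


@dataclass
class WeightedNaiveBayes:
    """Fitted attribute-weighted naive Bayes model.

    Use :meth:`fit` (or the module-level :func:`fit`) to train.  Attributes
    are categorical; classes are kept in canonical sorted order (ASD before
    TD) which also defines the final tie-break in :meth:`predict`.
    """

    smoothing: float = 1.0
    use_weights: bool = True
    classes: tuple[str, ...] = ()
    priors: dict[str, float] = field(default_factory=dict)
    n_attributes: int = 0
    # per attribute m: value -> {class -> conditional}, value -> {class -> W}
    conditionals: list[dict[Value, dict[str, float]]] = field(
        default_factory=list)
    weights: list[dict[Value, dict[str, float]]] = field(default_factory=list)
    class_counts: dict[str, int] = field(default_factory=dict)
    value_domains: list[tuple[Value, ...]] = field(default_factory=list)

    # ------------------------------------------------------------------ fit
    def fit(self, rows: Sequence[Row], labels: Sequence[str]
            ) -> "WeightedNaiveBayes":
        """Estimate priors, smoothed conditionals and Eq-style weights from
        a decision table (one row of subdecisions per training subject)."""
        if len(rows) == 0:
            raise ValueError("rows: empty decision table")
        if len(rows) != len(labels):
            raise ValueError(f"rows/labels: {len(rows)} rows vs "
                             f"{len(labels)} labels")
        arities = {len(r) for r in rows}
        if len(arities) != 1:
            raise ValueError(f"rows: inconsistent attribute counts {arities}")
        self.n_attributes = arities.pop()
        if self.n_attributes < 1:
            raise ValueError("rows: need at least one attribute")
        self.classes = tuple(sorted(set(labels)))
        if len(self.classes) < 2:
            raise ValueError(f"labels: need >= 2 classes, got "
                             f"{self.classes}")
        n = len(rows)
        self.class_counts = dict(Counter(labels))
        self.priors = {c: self.class_counts[c] / n for c in self.classes}

        lam = self.smoothing
        n_m = self.n_attributes
        self.conditionals, self.weights, self.value_domains = [], [], []
        for m in range(self.n_attributes):
            col = [r[m] for r in rows]
            values = tuple(sorted(set(col), key=repr))
            vc = Counter(zip(col, labels))           # n(d_m=v and c_i)
            v_count = Counter(col)                   # n(d_m=v)
            cond: dict[Value, dict[str, float]] = {}
            wt: dict[Value, dict[str, float]] = {}
            for v in values:
                cond[v] = {
                    c: (vc[(v, c)] + lam) /
                       (self.class_counts[c] + lam * len(values))
                    for c in self.classes}
                wt[v] = {}
                for c in self.classes:
                    if v_count[v] == 0:
                        wt[v][c] = 1.0
                    else:
                        wt[v][c] = (n_m + vc[(v, c)] / v_count[v]) / n_m
            self.conditionals.append(cond)
            self.weights.append(wt)
            self.value_domains.append(values)
        return self

    # ------------------------------------------------------- inference
    def _log_score(self, c: str, subdecisions: Row) -> float:
        score = math.log(self.priors[c])
        lam = self.smoothing
        for m, v in enumerate(subdecisions):
            cond = self.conditionals[m]
            if v in cond:
                p = cond[v][c]
                w = self.weights[m][v][c] if self.use_weights else 1.0
            else:
                # unseen value: smoothed zero-count conditional over an
                # enlarged domain; weight neutral
                k = len(self.value_domains[m]) + 1
                p = lam / (self.class_counts[c] + lam * k)
                w = 1.0
            score += math.log(p) + math.log(w)
        return score

    def posterior(self, subdecisions: Row) -> dict[str, float]:
        """Class posterior for one subdecision tuple (sums to 1)."""
        if not self.classes:
            raise ValueError("model: not fitted")
        if len(subdecisions) != self.n_attributes:
            raise ValueError(
                f"subdecisions: expected {self.n_attributes} attributes, "
                f"got {len(subdecisions)}")
        logs = {c: self._log_score(c, subdecisions) for c in self.classes}
        mx = max(logs.values())
        un = {c: math.exp(s - mx) for c, s in logs.items()}
        z = sum(un.values())
        return {c: u / z for c, u in un.items()}

    def predict(self, subdecisions: Row) -> str:
        """Most probable class; exact ties go to the larger prior, then to
        the first class in canonical order."""
        post = self.posterior(subdecisions)
        best = max(post.values())
        tied = [c for c in self.classes
                if math.isclose(post[c], best, rel_tol=1e-12, abs_tol=0.0)]
        if len(tied) > 1:
            top_prior = max(self.priors[c] for c in tied)
            tied = [c for c in tied
                    if math.isclose(self.priors[c], top_prior,
                                    rel_tol=1e-12, abs_tol=0.0)]
        return tied[0]

    def predict_many(self, rows: Sequence[Row]) -> list[str]:
        return [self.predict(r) for r in rows]

    # ---------------------------------------------------------- persistence
    def to_json(self) -> str:
        def enc(table):
            return [{repr(v): d for v, d in m.items()} for m in table]
        return json.dumps({
            "smoothing": self.smoothing,
            "use_weights": self.use_weights,
            "classes": list(self.classes),
            "priors": self.priors,
            "n_attributes": self.n_attributes,
            "class_counts": self.class_counts,
            "value_domains": [[repr(v) for v in d]
                              for d in self.value_domains],
            "conditionals": enc(self.conditionals),
            "weights": enc(self.weights),
        }, sort_keys=True)


def fit(rows: Sequence[Row], labels: Sequence[str], smoothing: float = 1.0,
        use_weights: bool = True) -> WeightedNaiveBayes:
    """Fit an attribute-weighted naive Bayes on a decision table."""
    return WeightedNaiveBayes(smoothing=smoothing,
                              use_weights=use_weights).fit(rows, labels)


def posterior(model: WeightedNaiveBayes, subdecisions: Row
              ) -> dict[str, float]:
    return model.posterior(subdecisions)


def predict(model: WeightedNaiveBayes, subdecisions: Row) -> str:
    return model.predict(subdecisions)
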
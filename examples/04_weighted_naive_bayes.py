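"""Attribute-weighted naive Bayes on a tiny decision table.

Each training row is a pair of subdecisions (here: from a physiological
and a behavioral branch) plus the true class.  The weighting coefficient
W(d_m=v | c) = [n(m) + n(d_m=v and c)/n(d_m=v)] / n(m) boosts attribute
values that are strongly associated with a class.
"""

from neurofuse import wnb

rows = [("ASD", "ASD"), ("ASD", "TD"), ("ASD", "ASD"), ("TD", "TD"),
        ("TD", "TD"), ("TD", "ASD"), ("ASD", "ASD"), ("TD", "TD")]
labels = ["ASD", "ASD", "ASD", "TD", "TD", "ASD", "ASD", "TD"]

model = wnb.fit(rows, labels)
print(f"priors: { {c: round(p, 3) for c, p in model.priors.items()} }")
print("weights of attribute 1 (physiological subdecision):")
for value, per_class in model.weights[0].items():
    print(f"  d1={value}: " +
          ", ".join(f"W(|{c})={w:.3f}" for c, w in per_class.items()))

for query in [("ASD", "ASD"), ("ASD", "TD"), ("TD", "ASD")]:
    post = model.posterior(query)
    print(f"query d1={query[0]}, d2={query[1]} -> "
          f"P(ASD)={post['ASD']:.3f}, predict {model.predict(query)}")
# Weights above 1 mark subdecision values that co-occur with a class more
# often than chance; the posterior multiplies them into the class scores.
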
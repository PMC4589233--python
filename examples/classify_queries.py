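"""Classify held-out sequences against a labeled reference set.

Builds a small synthetic 4-class family, holds one member of each class
out, and predicts its subtype with weighted k-NN at k=3.
"""

import homotype as ht

ds, _ = ht.generate(ht.SynthConfig(n_classes=4, per_class=6, seq_length=200,
                                   intra_identity=0.9,
                                   inter_identity_max=0.5, seed=7))
held = {r.id for r in ds if r.id.endswith("m00")}
training = ht.Dataset(r for r in ds if r.id not in held)
queries = ht.Dataset(r for r in ds if r.id in held)

predictions = ht.predict_batch(queries, training, k=3, scheme="weighted")

print(f"{'query':<12} {'true':<5} {'predicted':<10} top-neighbor  E-value")
for q, p in zip(queries, predictions):
    top_hit, _ = p.neighbors[0]
    print(f"{q.id:<12} {q.label:<5} {p.label:<10} "
          f"{top_hit.subject_id:<12} {top_hit.evalue:.2e}")

# Each query's class weight is the mean E-value of its neighbors in that
# class; the minimum-weight (closest-homology) class wins.  With classes
# separated below 50% identity, every held-out member is recovered.
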
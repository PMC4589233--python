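"""Gate candidate sequences with the PS00154 phosphorylation-site motif.

P-type ATPases carry the signature D-K-T-G-T-[LIVM]-[TI]; screening a mixed
set with it keeps only plausible pump sequences.
"""

import homotype as ht

pumps, _ = ht.generate(ht.SynthConfig(n_classes=3, per_class=3,
                                      seq_length=150, plant_motif=True,
                                      seed=3))
decoys = ht.Dataset(
    ht.SequenceRecord(id=f"decoy{i}", residues="MKVACDEFGHIKLMNPQRSTVWY" * 4)
    for i in range(3)
)
mixed = ht.Dataset(list(pumps) + list(decoys))

pattern = ht.parse_prosite(ht.PS00154)
kept = ht.screen(mixed, pattern)
print(f"screened {len(mixed)} sequences -> {len(kept)} motif-positive")

for rec in list(kept)[:3]:
    m = ht.scan(rec, pattern)[0]
    print(f"  {rec.id}: {m.matched} at positions {m.start}-{m.end}")

# All planted-motif records pass the gate and every decoy is rejected; the
# reported positions are 1-based inclusive, PROSITE-style.
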
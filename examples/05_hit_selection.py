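"""Tier-1 hit selection: high score in multiple conformations.

Selects compounds that rank in the top 10% of at least 3 of 5
conformation screens — the compounds most likely to bind across the
receptor's conformational ensemble.
"""

from ensdock import SynthConfig, make_score_table, select_hits

cfg = SynthConfig(seed=5, n_actives=120, n_decoys=2500, n_conformations=5)
table = make_score_table(cfg)

hits = select_hits(table, q=0.1, min_conformations=3)
n_active_hits = sum(cid in table.actives for cid in hits.df["compound_id"])
print(hits.df.head(10).to_string(index=False))
print(f"\n{len(hits.df)} compounds in the top 10% of >= 3/5 screens; "
      f"{n_active_hits} of them are planted actives "
      f"({100 * n_active_hits / len(hits.df):.0f}%).")
print("Requiring multiple conformations filters decoys that scored well once by chance.")
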
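"""Ensemble-docking enrichment analysis on a synthetic screen.

Generates a 120-active / 2500-decoy score table over 5 receptor
conformations in which only conformations 0-2 carry binding signal,
then reports top-10% recovery per conformation and which screens beat
the random baseline.
"""

from ensdock import (
    SynthConfig,
    aggregate,
    better_than_random,
    conformation_site_ranking,
    enrichment_curve,
    make_score_table,
    top_fraction_recovery,
)

cfg = SynthConfig(seed=5, signal_conformations=(0, 1, 2))
table = make_score_table(cfg)

curves = []
for conf, site in table.conformation_sites():
    ranking = conformation_site_ranking(table, conf, site)
    curves.append(enrichment_curve(ranking, table.actives, source=f"{conf}_{site}"))
    rec = top_fraction_recovery(ranking, table.actives, 0.1)
    print(f"conformation {conf}_{site}: top-10% recovery {rec.recovery_pct:5.1f}% "
          f"(EF {rec.enrichment_factor:.2f})")

best = aggregate(table, "best")
rec = top_fraction_recovery(best, table.actives, 0.1)
print(f"best-over-ensemble     : top-10% recovery {rec.recovery_pct:5.1f}% "
      f"(EF {rec.enrichment_factor:.2f})")

report = better_than_random(curves, at=0.1)
print(f"better than random at top 10%: {sorted(report.flagged_sources)}")
print("Random expectation is 10% recovery (EF 1); the three signal-bearing")
print("conformations recover most actives, the two null ones hover near 10%.")
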
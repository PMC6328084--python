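"""Structural-variant concordance: per-chromosome Jaccard, flags and S^c.

The pair below shares a clustered set of rearrangements on chr8 (the
pattern chromothripsis leaves) but disagrees on chr4. Each intra-chromosomal
event is weighted by the bases its breakpoints span; a translocation counts
1 base and half an event to each chromosome it joins.
"""

from concord import SvEvent, chromosome_jaccard_rows, make_sv_event, overall_concordance

cluster = [
    SvEvent("chr8", 40_000_000 + i * 300_000, "chr8", 40_100_000 + i * 300_000,
            cat)
    for i, cat in enumerate(["DEL", "INV", "DUP", "DEL", "INV", "DEL"])
]
tumour = cluster + [
    SvEvent("chr4", 10_000_000, "chr4", 12_000_000, "DEL"),
    make_sv_event("chr1", 5_000_000, "chr9", 8_000_000, "TRA"),
]
model = cluster + [
    SvEvent("chr4", 50_000_000, "chr4", 50_400_000, "DUP"),
    make_sv_event("chr1", 5_000_000, "chr9", 8_000_000, "TRA"),
]

rows = chromosome_jaccard_rows(tumour, model)
print(f"{'chrom':<7}{'T_bases':>10}{'P_bases':>10}{'C_bases':>10}"
      f"{'J':>7}  events(T/P)  flags")
for row in rows:
    j = "NA" if row.jaccard is None else f"{row.jaccard:.2f}"
    flags = []
    if row.elevated:
        flags.append("clustered>=5")
    if row.discordant_count:
        flags.append("count-diff>=10")
    print(f"{row.chrom:<7}{row.t_bases:>10.0f}{row.m_bases:>10.0f}"
          f"{row.shared_bases:>10.0f}{j:>7}  {row.t_events:>4.1f}/{row.m_events:<6.1f}"
          f"{','.join(flags)}")
score = overall_concordance(rows)
print(f"\nS^c = {score.positives}/{score.positives + score.negatives} "
      f"= {score.score:.2f}  (fraction of event-bearing chromosomes with J >= 0.6)")
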
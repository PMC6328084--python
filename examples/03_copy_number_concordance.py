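"""Ploidy-corrected copy-number concordance.

The model below is a whole-genome-doubled copy of the tumour except for one
amplified segment. Raw copy numbers disagree everywhere (2x), but after
rescaling each profile by its own ploidy the doubled genome scores as fully
concordant outside the truly divergent segment — the reason the pipeline
rescales before comparing.
"""

from concord import (
    CnSegment,
    SamplePloidy,
    cn_concordance,
    cn_concordance_by_chromosome,
    intersect_segments,
    ploidy_qc,
    rescale_by_ploidy,
)

tumour = [
    CnSegment("chr1", 0, 60_000_000, 2.0),
    CnSegment("chr1", 60_000_000, 100_000_000, 3.0),
    CnSegment("chr2", 0, 80_000_000, 2.0),
]
# doubled genome; the chr2 segment is additionally amplified beyond doubling
model = [
    CnSegment("chr1", 0, 60_000_000, 4.0),
    CnSegment("chr1", 60_000_000, 100_000_000, 6.0),
    CnSegment("chr2", 0, 80_000_000, 7.0),
]
t_ploidy = SamplePloidy("tumour", 2.0)
m_ploidy = SamplePloidy("model", 4.0)

print("ploidy QC:", ploidy_qc(t_ploidy, m_ploidy))
blocks = intersect_segments(
    rescale_by_ploidy(tumour, t_ploidy), rescale_by_ploidy(model, m_ploidy)
)
for conc in cn_concordance_by_chromosome(blocks):
    print(f"G_{conc.scope} = {conc.score:.3f} "
          f"(agree {conc.agree_bases:,} of {conc.t_bases + conc.m_bases - conc.union_bases:,} co-defined bases)")
genome = cn_concordance(blocks)
print(f"G_genome = {genome.score:.3f}")
print("\nAgreement = |rescaled difference| <= 0.25; G = I/(T+X-C).")
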
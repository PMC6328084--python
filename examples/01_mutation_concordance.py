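"""Mutation-set concordance for a toy tumour/xenograft pair.

Builds two small somatic call sets sharing some variants, then prints the
per-category and overall Jaccard indices. A Jaccard of 1 means the model
carries exactly the tumour's mutations in that category; 0 means none of
them; NA means the category is absent from both samples.
"""

from concord import VariantCall, jaccard_all_mutations, jaccard_by_type

shared = [
    VariantCall("chr12", 25_398_284, "C", "T", "Missense_Mutation"),  # KRAS G12D
    VariantCall("chr17", 7_577_120, "G", "A", "Missense_Mutation"),   # TP53
    VariantCall("chr1", 1_500_000, "A", "G", "Intron"),
    VariantCall("chr2", 2_400_000, "T", "C", "lincRNA"),
]
tumour_only = [
    VariantCall("chr3", 3_100_000, "G", "T", "Intron"),
    VariantCall("chr4", 4_700_000, "C", "A", "Silent"),
]
model_only = [
    VariantCall("chr5", 5_900_000, "T", "G", "Intron"),
]

tumour = shared + tumour_only
model = shared + model_only

print(f"{'category':<20}{'T':>4}{'P':>4}{'C':>4}  J")
for row in jaccard_by_type(tumour, model):
    print(f"{row.mutation_type:<20}{row.t_count:>4}{row.m_count:>4}"
          f"{row.shared:>4}  {row.jaccard:.3f}")
overall = jaccard_all_mutations(tumour, model)
print(f"{'All Mutations':<20}{overall.t_count:>4}{overall.m_count:>4}"
      f"{overall.shared:>4}  {overall.jaccard:.3f}")
print("\nT/P = calls in tumour/model, C = identical in both;"
      " J = C/(T+P-C) per annotation category.")
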
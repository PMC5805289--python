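"""Consensus deleteriousness calls at the standard three-tool thresholds.

A missense SNV is 'combinedly predicted deleterious' when SIFT < 0.05,
PolyPhen-2 HDIV > 0.957 and CADD phred >= 15 all hold; a missing score never
supports a call. The Venn decomposition shows how the three predictors
overlap — CADD scores non-coding variants too, so CADD-only calls dominate.
"""

from cvload import AnnotationRecord, VariantKey, classify_deleterious, predictor_venn

variants = [
    # (sift, polyphen, cadd, consequence)
    ("strong consensus missense", 0.01, 0.99, 28.0, "missense_variant"),
    ("CADD boundary (15 calls)", 0.04, 0.96, 15.0, "missense_variant"),
    ("SIFT at 0.05: strict, no call", 0.05, 0.99, 30.0, "missense_variant"),
    ("synonymous: consequence gate", 0.01, 0.99, 30.0, "synonymous_variant"),
    ("non-coding, CADD only", None, None, 22.0, "intron_variant"),
    ("benign missense", 0.60, 0.20, 3.0, "missense_variant"),
]

verdicts = []
for i, (label, sift, poly, cadd, cons) in enumerate(variants, start=1):
    rec = AnnotationRecord(
        key=VariantKey("1", i * 100, "A", "G"),
        sift=sift, polyphen_hdiv=poly, cadd_phred=cadd, consequence=cons,
    )
    v = classify_deleterious(rec)
    verdicts.append(v)
    print(f"{label:35s} sift={v.sift_call!s:5} polyphen={v.polyphen_call!s:5} "
          f"cadd={v.cadd_call!s:5} -> dSNV={v.combined}")

print("\npredictor Venn (disjoint regions over variants with >=1 call):")
for region, count in predictor_venn(verdicts).items():
    print(f"  {region}: {count}")
# Only the first two variants are dSNVs: all three tools agree AND the
# consequence is missense.
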
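"""Turn pileup variant lines into batch inputs for mutation-effect
predictors (SIFT, PolyPhen-2, firestar).

Each variant line yields one change record per non-reference allele; a
heterozygous call with two non-reference alleles yields two.
"""

from piletools import convert_stream, iter_gp_records, parse_pileup_line

pileup = [
    "chr1\t100\tA\tR\t40\t45\t60\t20\t....\tIIII",   # het A/G
    "chr1\t250\tC\tC\t40\t0\t60\t18\t....\tIIII",    # reference call: skipped
    "chr2\t77\tA\tK\t40\t50\t60\t22\t....\tIIII",    # het G/T, both non-ref
    "chrX\t9\tG\tT\t40\t38\t60\t15\t....\tIIII",     # hom T
]

for target in ("sift", "polyphen", "firestar"):
    records = iter_gp_records(iter(pileup), parser=parse_pileup_line)
    out = list(convert_stream(records, target))
    print(f"{target} ({len(out)} lines from {len(pileup)} pileup lines):")
    for line in out:
        print("   ", line)
    print()
print("the chr2 K call contributes two lines (alleles G and T); the reference",
      "call contributes none.")
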
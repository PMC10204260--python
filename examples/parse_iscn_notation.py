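"""Parse clinical array-CNV ISCN notation and derive the CNV type.

The lab's reports mix band-prefixed and chr-colon styles, hyphen and
underscore coordinate separators, and mosaic copy ranges such as x2~3
(duplication-triplication); the parser normalizes all of them.
"""

from cnvreclass import CopyState, Sex, format_iscn, infer_type, parse_iscn

strings = [
    "arr [hg19] chr1:(145818702-147824207)x3 dn",
    "Xq27.1(139103383_139801281)x2",
    "Xq27.1(139103383-139763381)x2~3",
    "15q11.2(22765628-23191062)x1",
]

for text in strings:
    for rec in parse_iscn(text):
        print(f"input:      {text}")
        print(f"canonical:  {format_iscn(rec)}")
        print(f"locus:      chr{rec.chrom} {rec.start:,}-{rec.end:,} "
              f"({rec.interval.length / 1000:.0f} kb), copies {rec.copy_state}, "
              f"build {rec.assembly.value}"
              + (f", inheritance {rec.inheritance.value}" if rec.inheritance else ""))
        print()

# Copy state relative to expected ploidy gives loss/gain; on chrX the
# patient's sex matters: one copy on a female X is a deletion.
t = infer_type(CopyState(1, 1), "X", Sex.F)
print(f"x1 on chrX in a female -> {t.value} (expected ploidy 2)")
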
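"""Convert CNV coordinates between genome builds with a UCSC chain file.

Early-era aCGH results were reported on NCBI36/hg18 and must be lifted to
GRCh37/hg19 before annotation.  This example writes a tiny chain that
shifts chr1 by +250 bp and round-trips an interval through it.
"""

import tempfile
from pathlib import Path

from cnvreclass import Assembly, GenomicInterval, lift_interval, read_chain

SIZE = 249_250_621
tmp = Path(tempfile.mkdtemp())
fwd = tmp / "hg18ToHg19.over.chain"
fwd.write_text(
    f"chain 1000 chr1 {SIZE} + 0 1000000 chr1 {SIZE} + 250 1000250 1\n1000000\n\n"
)
back = tmp / "hg19ToHg18.over.chain"
back.write_text(
    f"chain 1000 chr1 {SIZE} + 250 1000250 chr1 {SIZE} + 0 1000000 1\n1000000\n\n"
)

interval = GenomicInterval("1", 10_001, 60_000, Assembly.HG18)
out = lift_interval(interval, read_chain(fwd))
print(f"hg18 {interval}  ->  hg19 {out.mapped_interval} "
      f"(status {out.status.value}, {out.mapped_fraction:.0%} of bases aligned)")

rt = lift_interval(out.mapped_interval, read_chain(back))
print(f"hg19 {out.mapped_interval}  ->  hg18 {rt.mapped_interval} "
      f"(round trip recovers the original interval: "
      f"{(rt.mapped_interval.start, rt.mapped_interval.end) == (interval.start, interval.end)})")
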
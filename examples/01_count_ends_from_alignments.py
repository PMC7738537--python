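"""Build strand-specific read-end count tracks from a small BED of alignments.

dRNA-Seq libraries mark transcript 5' ends, so we count the 5'-most mapped
position of each read; Term-Seq reads sequence the 3' end antisense, so
their strands are inverted before counting 3' ends.
"""

from pathlib import Path
import tempfile

import txends as tx

replicons = [tx.Replicon("chr1", 1000)]

bed = Path(tempfile.mkdtemp()) / "reads.bed"
bed.write_text(
    "chr1\t99\t150\tr1\t0\t+\n"   # transcript starting at position 100
    "chr1\t99\t150\tr2\t0\t+\n"
    "chr1\t99\t151\tr3\t0\t+\n"
    "chr1\t400\t460\tr4\t0\t-\n"  # Term-Seq read: antisense to its transcript
)

drna = tx.count_ends(tx.read_alignments(bed, replicons), tx.FIVE_PRIME, replicons)
plus = drna[("chr1", "+")]
print(f"dRNA-Seq 5' ends on + strand: {plus.counts.sum()} reads, "
      f"count at position 100 = {plus.counts[99]}")
# Three reads share the 5' end at position 100: a candidate TSS pile-up.

term_reads = (tx.invert_termseq_read(r) for r in tx.read_alignments(bed, replicons))
term = tx.count_ends(term_reads, tx.THREE_PRIME, replicons)
print(f"Term-Seq 3' end after inversion: + strand count at 460 = "
      f"{term[('chr1', '+')].counts[459]}")
# The - strand alignment 401..460 inverts to + and its 3' end (position 460)
# marks the transcript's termination point.
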
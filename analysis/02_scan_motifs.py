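#!/usr/bin/env python
"""Scan the synthetic genome for C4 motifs and compare against the truth.

Reports planted-motif recovery (sensitivity, false positives, coordinate
agreement) and the per-class PQS content of the genome, writing
results/tables/motif_recovery.tsv and motif_hits.bed.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from c4map import formats, seqscan


def main() -> None:
    common.ensure_genome()
    (record,) = formats.read_fasta(common.GENOME_FA)
    truth = formats.read_bed(common.TRUTH_BED)

    hits = seqscan.scan_c4(record.sequence, min_tracts=4)
    hit_set = seqscan.hits_to_peakset(hits, record.id, label="C4_hits")
    formats.write_bed(hit_set, common.TABLES / "motif_hits.bed")

    got = {(h.start, h.end, h.strand) for h in hits}
    want = {(iv.start, iv.end, iv.strand) for iv in truth}
    rows = [
        {
            "n_planted": len(want),
            "n_hits": len(got),
            "true_positives": len(got & want),
            "false_positives": len(got - want),
            "false_negatives": len(want - got),
            "exact_recovery": got == want,
        }
    ]
    df = pd.DataFrame(rows)
    df.to_csv(common.TABLES / "motif_recovery.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    if got == want:
        print("=> the scanner recovers every planted C4 at its exact "
              "coordinates with zero false positives")

    # PQS landscape of the same genome on the G-rich strand classes
    counts = {
        cls: len(seqscan.scan_pqs(record.sequence, cls))
        for cls in seqscan.PQS_CLASSES
    }
    pd.DataFrame([counts]).to_csv(
        common.TABLES / "pqs_class_counts.tsv", sep="\t", index=False
    )
    print("PQS class hit counts:", counts)


if __name__ == "__main__":
    main()
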
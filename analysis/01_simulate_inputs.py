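#!/usr/bin/env python
"""Generate all synthetic inputs for the downstream analyses.

Writes, under scratch/analysis/: a 1-Mb genome with 50 planted C4 motifs
(FASTA + truth BED + chrom.sizes), a 200/220 peak pair constructed with an
86.5% A-in-B overlap, three Poisson coverage tracks (two replicates sharing
one peak set, one from an unrelated set), and six EMSA titration tables
(noiseless and sigma = 0.05) at the three dissociation constants the
binding analysis recovers.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common


def main() -> None:
    common.ensure_genome(force=True)
    common.ensure_peaks_and_tracks(force=True)
    common.ensure_titrations(force=True)
    print(f"genome: {common.GENOME_FA} ({common.GENOME_LEN:,} bp, "
          f"{common.N_PLANTED_C4} planted C4 motifs; truth {common.TRUTH_BED.name})")
    print(f"peaks:  {common.PEAKS_A.name}/{common.PEAKS_B.name} "
          "(200/220 peaks, 86.5% A-in-B overlap by construction)")
    print(f"tracks: {common.TRACK_1.name}, {common.TRACK_2.name} (shared peaks), "
          f"{common.TRACK_OTHER.name} (independent)")
    print("titrations: 3 Kd values x {noiseless, sigma=0.05} under "
          f"{common.SCRATCH}")


if __name__ == "__main__":
    main()
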
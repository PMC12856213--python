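"""Shared paths and input generation for the numbered analysis drivers.

Bulky simulated inputs (FASTA, bedGraph) live under scratch/analysis and
are regenerated deterministically when missing; small summary tables go to
results/tables.
"""

from __future__ import annotations

from pathlib import Path

from c4map import formats, isotherm, synth

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
TABLES = ROOT / "results" / "tables"

SEED = 2025
GENOME_LEN = 1_000_000
N_PLANTED_C4 = 50
COVERAGE_SIZES = {"chr1": 6_000_000}
KDS_NM = {"range_low": 10.79, "range_high": 84.86, "hairpin_prone": 394.1}

GENOME_FA = SCRATCH / "genome.fa"
TRUTH_BED = SCRATCH / "planted_c4.bed"
CHROM_SIZES = SCRATCH / "genome.chrom.sizes"
PEAKS_A = SCRATCH / "peaks_probeA.bed"
PEAKS_B = SCRATCH / "peaks_probeB.bed"
TRACK_1 = SCRATCH / "coverage_rep1.bedgraph"
TRACK_2 = SCRATCH / "coverage_rep2.bedgraph"
TRACK_OTHER = SCRATCH / "coverage_other.bedgraph"


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    TABLES.mkdir(parents=True, exist_ok=True)


def ensure_genome(force: bool = False):
    ensure_dirs()
    if force or not (GENOME_FA.exists() and TRUTH_BED.exists()):
        truth = synth.make_genome(
            1, GENOME_LEN, {"C4": N_PLANTED_C4}, gc=0.41, seed=SEED
        )
        formats.write_fasta(truth.genome, GENOME_FA)
        formats.write_bed(truth.planted, TRUTH_BED)
        CHROM_SIZES.write_text(
            "".join(f"{c}\t{n}\n" for c, n in truth.chrom_sizes().items())
        )


def ensure_peaks_and_tracks(force: bool = False):
    ensure_dirs()
    if force or not all(
        p.exists() for p in (PEAKS_A, PEAKS_B, TRACK_1, TRACK_2, TRACK_OTHER)
    ):
        a, b = synth.make_peak_pair(
            200, 220, 0.865, COVERAGE_SIZES, seed=SEED + 1
        )
        formats.write_bed(a, PEAKS_A)
        formats.write_bed(b, PEAKS_B)
        shared = synth.SynthTrackTruth(a, enrichment=10.0, background_rate=10.0, seed=0)
        other_peaks, _ = synth.make_peak_pair(200, 220, 0.0, COVERAGE_SIZES, seed=SEED + 2)
        other = synth.SynthTrackTruth(other_peaks, 10.0, 10.0, seed=0)
        for truth, path, seed in [
            (shared, TRACK_1, SEED + 3),
            (shared, TRACK_2, SEED + 4),
            (other, TRACK_OTHER, SEED + 5),
        ]:
            track = synth.make_coverage(truth, COVERAGE_SIZES, bin_size=50, seed=seed)
            formats.write_bedgraph(track, path)


def titration_path(name: str) -> Path:
    return SCRATCH / f"titration_{name}.tsv"


def ensure_titrations(force: bool = False):
    ensure_dirs()
    for i, (name, kd) in enumerate(KDS_NM.items()):
        for noise, tag in [(0.0, "noiseless"), (0.05, "noisy")]:
            p = titration_path(f"{name}_{tag}")
            if force or not p.exists():
                s = synth.make_titration(kd, noise_sd=noise, seed=SEED + 10 + i)
                isotherm.write_titration_table(s, p)
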
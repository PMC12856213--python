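# c4map

Indirect mapping of genomic G-quadruplexes (G4s) through the complementary
C-rich single strand.

When the G-rich strand of genomic DNA folds into a G4, the complementary
C-rich strand (**C4**) is left exposed as single-stranded DNA. A small
engineered probe that binds C-rich ssDNA therefore reports G4 formation
indirectly — from the strand the G4 displaces rather than the structure
itself. `c4map` implements the quantitative workflow behind that
strategy, for genomicists and biochemists who want to reproduce or extend
its analyses:

* **Motif grammars** (`c4map.seqscan`) — the probe's recognition unit
  CCCN₁₋₇CCC (or a single run of ≥ 7 C), full C4 motifs (2–4 maximal
  C≥3 tracts joined by 1–7 nt loops), and five putative-G4 (PQS) classes
  on the G-rich strand (canonical, two-quartet, G-vacancy, long-loop,
  bulged), scanned strand-aware with deterministic greedy resolution.
* **Binding thermodynamics** (`c4map.isotherm`) — EMSA quantification
  with the tight-binding (ligand-depletion) isotherm

      Y(X) = [T0 + X + Kd − √((T0 + X + Kd)² − 4·T0·X)] / (2·T0),

  required because the labelled DNA (T0 = 20 nM) is not dilute relative
  to the nanomolar Kd values being measured; deterministic least-squares
  Kd estimation and a residual-bootstrap 95% CI.
* **Colocalization statistics** (`c4map.coloc`) — RPGC (1×-coverage)
  normalization, Pearson correlation over fixed genomic bins with
  blacklist and outlier handling, asymmetric peak-overlap fractions,
  multiway exclusive ("upset") intersection counts, peak-centered signal
  profile matrices, and promoter (TSS ± 3 kb) partitioning.
* **Synthetic benchmarks** (`c4map.synth`) — seeded generators for
  genomes with planted motifs (exhaustive truth BEDs), peak pairs with an
  exactly controlled overlap fraction, Poisson coverage tracks, and
  titration tables — so every analysis stage is testable without any
  sequencing download.

## Worked example

Scan a sequence containing the telomeric C-rich repeat, then fit a Kd
from a simulated titration:

```python
>>> from c4map.seqscan import scan_c4
>>> hits = scan_c4("CCCTAACCCTAACCCTAACCC", min_tracts=4)
>>> [(h.start, h.end, h.strand, h.n_tracts, h.spacer_lengths) for h in hits]
[(0, 21, '+', 4, (3, 3, 3))]
```

One C4 hit spanning the whole repeat: four C₃ tracts with three 3-nt
loops, on the strand given (`+`).

```python
>>> from c4map.synth import make_titration
>>> from c4map.isotherm import fit_kd
>>> series = make_titration(Kd=84.86, T0=20.0, noise_sd=0.0)
>>> fit = fit_kd(series)
>>> round(fit.Kd, 2), fit.converged
(84.86, True)
```

The noiseless 8-point titration (protein at 0–1000 nM over 20 nM DNA)
refits its planted dissociation constant exactly: Kd = 84.86 nM.

The same operations are available from the shell:

```sh
c4map scan --fasta genome.fa --class C4 --min-tracts 4 --out hits.bed
c4map gen titration --kd 84.86 --out t.tsv && c4map fitkd --table t.tsv --t0 20
c4map overlap --a g4_probe_peaks.bed --b c4_probe_peaks.bed
```

## Analysis drivers

The `analysis/` scripts run the full synthetic study end to end, writing
summary tables to `results/tables/` (bulky intermediates go to
`scratch/`):

1. `01_simulate_inputs.py` — genome with 50 planted C4 motifs, peak pair
   with 86.5% overlap, three coverage tracks, six titration tables.
2. `02_scan_motifs.py` — planted-motif recovery (50/50 exact, zero false
   positives) and the genome's PQS class census.
3. `03_fit_binding.py` — noiseless and noisy Kd fits with bootstrap CIs.
4. `04_colocalization.py` — overlap fraction, upset counts, the
   300-bp-bin correlation matrix (replicates r ≈ 0.93, unrelated track
   r ≈ 0.00), profile matrix and promoter partition.

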
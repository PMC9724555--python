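# ibdbench

Benchmarking framework for identity-by-descent (IBD) segment detection.

Detectors such as hap-IBD, iLash, RaPID, TPBWT and FastSMC report pairwise
IBD segments from phased haplotype panels. Their calls cannot be scored with
plain precision/recall: a reported segment may be partially true, a true
segment may come back split into pieces, and performance depends strongly on
segment length. `ibdbench` provides the full evaluation stack for anyone
developing or choosing such a detector:

* **Ground truth from genealogies** — extract true IBD segments from
  coalescent local trees (tskit/msprime tree sequences, or the package's own
  text track format) as maximal runs where a haplotype pair keeps the same
  most recent common ancestor (MRCA), sampled every 5,000 bp and kept when at
  least 1 cM long.
* **Controlled test panels** — multiallelic/singleton site filtering,
  array-density downsampling (two-pass highest-MAF selection over even cM
  intervals), and incremental genotyping-error injection at exact marginal
  rates.
* **Six evaluation metrics** on genetic coordinates, length-stratified with
  full-set references, plus per-site coverage profiles and
  relatedness-degree calls from total pairwise sharing.

## The metrics

For a reported segment $r$, its best-matching truth segment is the one with
the longest cM overlap $\omega(r)$ (same haplotype pair only). With
$|\cdot|$ the genetic length:

* **accuracy** $= \frac{1}{n_R}\#\{r : \omega(r) \ge 0.5\,|r|\}$ — the
  fraction of calls at least half covered by a single truth segment
  ($1-$accuracy is the false-positive fraction);
* **length accuracy** $= \frac{1}{n_R}\sum_r \omega(r)/|r|$;
* **length discrepancy** $= \sqrt{\mathrm{mean}_r\,(|r| - |t_r|)^2}$ (RMS,
  over matched calls, against the best-matching truth length $|t_r|$);
* **recall** $= \frac{1}{n_T}\#\{t : \omega(t) \ge 0.5\,|t|\}$ for truth
  segments $t$ against their single best reported match;
* **power** $= \frac{1}{n_T}\sum_t \omega(t)/|t|$;
* **accumulative power** — like power, but crediting the merged union of
  *all* reported segments overlapping $t$.

Reports stratify by segment length (default bins $[2,3), [3,4), \dots,
[7,\infty)$ cM) while always matching against the *full* opposite set, so a
2.9 cM call of a 3.0 cM truth segment still scores as accurate inside its
bin.

## Worked example

```python
from ibdbench import (GeneticMap, HaplotypeId, HapPair,
                      evaluate_reported, evaluate_truth, segment_from_bp)

gmap = GeneticMap.uniform(30_000_000)          # 1 cM/Mb
pair = HapPair(HaplotypeId("A", 0), HaplotypeId("B", 0))
truth    = [segment_from_bp(pair, "1", 0, 10_000_000, gmap)]          # 10 cM
reported = [segment_from_bp(pair, "1", 0, 4_000_000, gmap),           # 4 cM
            segment_from_bp(pair, "1", 5_000_000, 9_000_000, gmap)]   # 4 cM

print(evaluate_reported(reported, truth))   # (1.0, 1.0, 6.0)
print(evaluate_truth(truth, reported))      # (0.0, 0.4, 0.8)
```

Both fragments are fully inside the truth segment, so every call is accurate
(accuracy and length accuracy 1.0) but each is 6 cM shorter than its best
match (RMS discrepancy 6.0 cM). On the truth side the best single fragment
covers only 4/10 < 50% (recall 0.0, power 0.4), while the two fragments
together cover 8/10 of the segment (accumulative power 0.8) — exactly the
fragmentation signature the six metrics are designed to separate.

The full pipeline runs from a YAML config; with no inputs configured it
simulates its own seeded benchmark (200 haplotypes over 10 Mb by default)
and degrades the truth with a pseudo-caller:

```bash
ibdbench all --seed 1 --outdir bench_out
```

writes `sim.truth.tsv`, `sim.reported.tsv`, `array.vcf`,
`errors_0.001.vcf`, `coverage.tsv`, `relatedness.tsv` and `metrics.tsv`:

```text
bin     accuracy      length_accuracy  length_discrepancy_cm  recall        power         accumulative_power  n_reported  n_truth
all     0.97551696    0.9492132858     0.8525551071           0.7772970605  0.8161404092  0.8748818339        86999       73039
[2,3)   0.9754909091  0.9532182286     0.5929987205           0.781742126   0.8329181252  0.900464835         13750       16256
...
```

Scoring a real detector instead: point `calls:` at its output file
(`calls_dialect: hapibd` for hap-IBD's 8-column TSV, or a custom column map
for other tools) and `truth_file:`/`genetic_map:` at your truth set and map,
then run `ibdbench eval`.

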
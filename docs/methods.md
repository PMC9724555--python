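# Methods

This note documents the models and procedures `ibdbench` implements, the
parameters that matter, and the design choices made where more than one
reasonable convention exists.

## Coordinates and domain objects

All segments are half-open physical intervals `[start_bp, end_bp)` on a
single chromosome; genetic bounds are obtained by piecewise-linear
interpolation of a genetic map and the genetic length is
`cm(end) − cm(start)`. Positions outside the mapped range clamp to the
terminal cM values rather than extrapolating — sparse maps would otherwise
produce inflated or negative lengths. Haplotype pairs are unordered and
canonicalized lexicographically on `(sample_id, hap_index)`; panels are
single-chromosome (the strictly-increasing-position invariant enforces
this, and multi-chromosome input is a hard error rather than a silent
merge).

Two comparison modes exist: `haplotype` (default — segments match only
within the identical unordered haplotype pair) and `individual` (the four
haplotype combinations of a sample pair are pooled, for detectors that do
not emit haplotype indices). Pairs formed by the two haplotypes of one
sample are excluded by default everywhere; they describe inbreeding-style
MRCA sharing that standard detectors do not report, and can be enabled
explicitly.

## Ground-truth extraction

Two haplotypes are IBD where they keep the same MRCA in every local tree.
The extractor samples local trees on a regular grid (`sample_step_bp`,
default 5,000 bp), takes maximal runs of identical MRCA labels per pair,
and keeps runs of at least `min_length_cm` (default 1 cM). Segment bounds
sit on the sampling grid: a run starts at its first sampled position and
ends at the first sampled position after it, except that the terminal run
closes at the region end so the last segment is not truncated by up to one
step. An `exact` boundary mode using the track's true breakpoints is
available; the sampled mode is the default because it reproduces the
benchmark's discretization, and refining the grid only sharpens boundaries
(never merges segments — detected label changes persist on any finer grid
that contains the coarse one).

MRCA identity is label equality within one track; labels are opaque, so
two adjacent trees whose MRCA node changes but TMRCA stays equal count as
different ancestors. Positions where a pair has no common ancestor
(multi-root trees) are excluded from segments.

A brute-force oracle (`extract_truth_ibd_oracle`, plain per-position run
accumulation) ships in the package and must agree exactly with the
vectorized extractor; the test suite checks this on randomized tracks.

## Panel construction

* **Site filter** — sites with more than two observed allele values are
  removed, as are sites whose minor allele count is ≤ 1 (singletons and
  monomorphic sites). Idempotent.
* **Array downsampling** — the chromosome's mapped genetic length is split
  into `target_sites` intervals of width `I = total_cM / target_sites`
  grouped into windows of `w` intervals (default target 17,197 — the UK
  Biobank chromosome-20 array marker count used as reference density — and
  `w = 5`). Pass 1 gives each interval its highest-MAF site; pass 2 walks
  the empty intervals left to right and fills each with the best unused
  site of its window until leftovers run out. MAF ties break toward the
  lower bp position, making selection deterministic; a final partial
  window is processed with whatever intervals it has. Output never exceeds
  the target and is measurably more evenly spaced than random selections
  of the same size.
* **Genotyping errors** — each haploid allele call flips `0↔1`
  independently so the marginal error rate is exactly `rate`. "Per
  genotype" rates are interpreted per haplotype allele because errors are
  implanted on the phased panels detectors consume; users who read the
  rate per diploid genotype can halve it. Incremental chains (0.1% →
  0.2% → …) pass the previous error set as `base_errors`; new flips are
  drawn only on untouched cells with probability `(r₂ − r₁)/(1 − r₁)`,
  where `r₁` is the realized base fraction, so error sets are nested and
  the expected marginal rate is exactly `r₂` without double-flipping.
* **Haplotype merging** — consecutive haplotype columns `(2k, 2k+1)`
  collapse to one unphased genotype (ALT dosage), the input expected by an
  external rephasing step. The rephasing itself (and switch-error scoring)
  is out of scope; the framework consumes already-perturbed panels.

The pipeline default applies filtering → downsampling → error injection;
the stages are plain functions, so any other order can be composed.

## Evaluation metrics

See the README for definitions. Decisions that the definitions leave open:

* Coverage for accuracy/recall uses a **single** best-matching segment,
  never a union; accumulative power is the only union-based metric, and it
  merges overlapping reported intervals before summing so shared coverage
  is not double-counted.
* Unmatched reported segments contribute 0 to length accuracy (the mean is
  over **all** reported segments) and are excluded from the discrepancy
  RMS, which is defined via a best match that does not exist for them; a
  flag charges them their full length instead.
* Best-match ties on overlap break toward the candidate with the smaller
  absolute length difference, then the earlier start. Ties can only affect
  the discrepancy, never accuracy or power.
* The 50% coverage threshold is boundary-inclusive ("at least 50%").
* Length bins default to `[2,3), [3,4), [4,5), [5,6), [6,7), [7,∞)` cM —
  the `[6,7)` bin is included for contiguity; any strictly increasing edge
  list is accepted, so the variant without it is one config line away.
  Binned evaluation always matches against the full opposite set
  (`reference="full"`); the per-bin-reference scheme is implemented only
  as a comparison mode because it misclassifies near-boundary matches.
* Metrics are computed on genetic coordinates only; variant-site-based
  overlap (more natural for IBD mapping) is out of scope.

A naive all-pairs oracle implementation of all six metrics lives in
`synthdata` (independent code path, no shared logic with the engine) and
the engine must reproduce it exactly — this anti-circularity rule is the
backbone of the test suite.

## Summaries

* **Coverage profiles** count, at each panel marker position, the segments
  of length ≥ 2 cM (configurable) containing it, half-open on the right.
  Profiles are computed at marker positions rather than a uniform grid so
  truth and detector profiles are directly comparable.
* **Relatedness** — total cM shared by a sample pair (all four haplotype
  combinations summed) gives a kinship estimate
  `φ = total / (4 · genome_cM)`; degree `d` is assigned when
  `φ ∈ (2^−(d+3/2), 2^−(d+1/2)]` (inclusive upper edge → boundary values
  go to the closer relation), degree 0 marking duplicate/monozygotic
  pairs and anything below the degree-4 lower bound unrelated. These are
  the standard powers-of-two kinship ranges; they are fully overridable
  and deliberately not adjusted for detector power loss, so degraded
  calls show up as shifted degree histograms rather than being hidden by
  recalibration.

## Synthetic data

The generators define the conditions every test runs under:

* `gen_track` draws, per haplotype pair, independent piecewise-constant
  MRCA labels with Exponential(`mean_segment_bp`, default 1 Mb) breakpoint
  spacing over the region (default 10 Mb at 1 cM/Mb). It reproduces the
  run structure truth extraction consumes but is **not** coalescently
  consistent across pairs, and its IBD length distribution is not
  demographically calibrated — tests passing on it validate the machinery,
  not any population-genetic expectation.
* `gen_panel` draws site MAFs from a stated distribution (default
  Uniform(0.05, 0.5)) with independent Bernoulli alleles; there is no
  linkage disequilibrium, which is irrelevant for the site-selection and
  error-injection operations it feeds.
* `gen_scenario` is the pseudo-caller: truth segments per pair (default
  lengths Uniform(2, 10) cM), degraded by drops, midpoint fragmentation
  with a gap, uniform boundary jitter, and appended false positives —
  the failure modes real detectors exhibit (fragmenting long segments,
  trimming boundaries, spurious short calls). Segment placement happens
  in cM, is rounded to integer bp, and the cM bounds are then re-derived
  from the map so all coordinates stay map-consistent.

All randomness flows from one integer seed per generator call through a
named `numpy.random.Generator`; there is no global random state, and the
CLI derives per-stage seeds from the single configured seed.

## Pipeline and reproducibility

The `ibdbench` CLI exposes `simulate`, `truth`, `downsample`, `errors`,
`eval`, `coverage`, `relatedness` and `all` over a YAML config whose
defaults encode the standard protocol (5,000 bp sampling, 1 cM truth
minimum, 50% threshold, 2 cM coverage cutoff, `w = 5`). Every run writes a
manifest with a short configuration hash (computed from the loaded config,
excluding the output directory) and stamps that hash into each data
artifact; reruns with the same config and seed are byte-identical, with
timestamps confined to the log stream. Problem sizes used by the default
simulation and the acceptance script (200 and 100 haplotypes over 10 Mb,
20,000-site panels, 10⁶-cell error matrices, 200–1,000 metric scenarios)
were chosen as the smallest scales at which every distributional check is
well-powered.

## Known limitations

* Truth extraction is quadratic in haplotype count (all pairs); biobank
  scale requires restricting the pair set.
* The error model is a uniform allele flip: no nucleotide- or
  region-specific profiles, and no falsely called non-variant sites (the
  singleton filter would remove most of those).
* Tree-sequence input assumes diploid samples (paired sample nodes).
* Running the IBD detectors themselves, demographic simulation recipes,
  rephasing, and run-time/memory harnesses are out of scope; the
  framework consumes their inputs and outputs.
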
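# adakde

Kernel density signal reconstruction for mapped sequencing reads.

`adakde` rebuilds the genome-wide signal underlying single-end read data
(e.g. ChIP-Seq) as a probability distribution over integer base pairs. It
implements:

* **Fixed- and adaptive-bandwidth kernel density estimates** — the estimate
  at a position is the average of truncated kernels centered at the read
  positions, `f(x) = (1/n) Σᵢ K(x − xᵢ, hᵢ)`.
* **Three kernel shapes** — gaussian (truncated at ±5h), square (±3h) and
  triangle (±6h), each normalized to sum to one over the integer offsets in
  its support, with `h` calibrated so every shape has standard deviation ≈ h.
* **k-nearest-neighbor bandwidth rules** — KNN1 (distance to the k-th
  nearest neighbor) and KNN2, which overrides KNN1 with the distance to the
  nearest opposite-side point whenever all k neighbors fall on one side.
  KNN2 guarantees a strictly positive density everywhere between the
  extreme data points, avoiding the "zero problem" of held-out scoring.
* **Uniform blending** — `f_ε = (1 − ε) f + ε/G` gives every position
  baseline mass on a chromosome of length G.
* **Held-out tuning** — a seeded 50/25/25 train/tune/test split; `h` or `k`
  is chosen to maximize the mean natural-log probability of the tuning
  points, and test performance is reported as the geometric-mean
  probability.
* **Exact sparse tracks** — the square-kernel estimate as a
  piecewise-constant track (≤ 2n+1 pieces, built by an event sweep in time
  independent of G) and the triangle-kernel estimate as a piecewise-linear
  track whose interpolation reproduces the dense values.
* **Strict local maxima** — positions `b` with `f(b) > f(b±1)`, with height
  histograms and BED/TSV export.
* **A read simulator** — point sources with normal spread plus uniform
  background, strand-displaced by half a fragment length, with the exact
  generating density available as ground truth.

Reads come from BAM/SAM (via pysam) or a 3-column `chrom pos strand` text
format; tracks are written as bedGraph or fixedStep WIG.

## Command line

```sh
# synthetic dataset with known truth
adakde simulate --g 1000000 --n-reads 20000 --fragment-length 200 \
    --sources "300000:0.5:50,700000:0.45:200" --background-weight 0.05 \
    --seed 1 --out reads.txt

# adaptive-bandwidth gaussian track (KNN2, k=7), blended with eps=0.1
adakde density --reads reads.txt --chrom chr1 --chrom-length 1000000 \
    --fragment-length 200 --kernel gaussian --rule knn2 --k 7 \
    --epsilon 0.1 --out track.bedGraph

# tune h (or k with --param k) on held-out data
adakde tune --reads reads.txt --chrom chr1 --chrom-length 1000000 \
    --fragment-length 200 --param h --grid default --seed 1 \
    --report tuning.tsv

# strict local maxima of a track
adakde maxima --in track.bedGraph --chrom chr1 --chrom-length 1000000 \
    --out-bed maxima.bed --out-tsv maxima.tsv

# five-way held-out comparison (fixed h=16, tuned fixed h, tuned adaptive
# gaussian/triangle/square)
adakde compare --reads reads.txt --chrom chr1 --chrom-length 1000000 \
    --fragment-length 200 --seed 1 --out comparison.tsv
```

Defaults: `--epsilon 0.1`, `--kernel gaussian`, `--rule knn2`; the default
bandwidth grid is the half-integer powers of two 2^(j/2), j = 4..30, and
the default k grid is 1..32.

## Layout

* `src/adakde/kernels.py` — kernel shapes, discrete normalization
* `src/adakde/bandwidths.py` — KNN1/KNN2 bandwidth rules
* `src/adakde/density.py` — dense/piecewise estimates, blending, queries
* `src/adakde/tuning.py` — splits, mean-log-probability scoring, grids
* `src/adakde/maxima.py` — strict local maxima, histograms, BED export
* `src/adakde/reads_io.py` — BAM/text input, preprocessing, bedGraph/WIG
* `src/adakde/simulate.py` — synthetic reads and ground-truth density
* `src/adakde/cli.py` — the `adakde` command
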
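# Methods

## The descriptor

A DNA sequence `s` of length `n` over {A, C, G, T} is summarised by the
occurrence frequencies of ordered nucleotide pairs at a range of
separations.  For a separation distance `d >= 1` (with `d = 1` meaning
adjacent; X and Y are separated by `d - 1` intervening nucleotides),
every position `i` in `[1, n - d]` contributes the ordered pair
`(s[i], s[i + d])`.  There are 16 ordered pairs, kept in the frozen
order

    Ω = (AT, AA, AC, AG, TT, TA, TC, TG, GT, GA, GC, GG, CT, CA, CC, CG)

so that every serialized artifact is byte-reproducible.  The counts at
separation `d` sum to `n - d`; dividing by `n - d` gives a
16-dimensional frequency vector `f^(d)` on the probability simplex.
Stacking `f^(1) .. f^(d0)` row-wise gives the `d0 x 16` frequency
matrix `F(s)`; flattening row-major (the `d = 1` block first) gives the
`16 * d0`-dimensional frequency vector `F̂(s)`.  Pairs overlap freely: a
position can be the X of one pair and the Y of another.  The descriptor
is strand-specific by design — AT and TA are distinct coordinates, and
no reverse-complement symmetrisation is applied.

## The depth bound

The X-positions live in `[1, n - d]` and the Y-positions in
`[d + 1, n]`.  These windows overlap on `[d + 1, n - d]`; requiring the
overlap to cover at least half the sequence, `(n - 2d)/n >= 1/2`, gives
the default cap `d <= floor(n / 4)`.  Profiles deeper than the cap can
be requested explicitly (`enforce_bound=False` / `--d0 K`), with a
warning, up to `d0 = n - 1`.  For a set of sequences compared jointly,
one shared depth

    d0 = min over the set of floor(n / 4)

is used so all profiles have identical shape.  Longer sequences are
never truncated: all their positions contribute pairs at every
`d <= d0`, so a longer sequence's deeper composition still informs its
profile.

## Distance measures

Two measures compare profiles:

* city-block `d1(s, h) = Σ_ij |F_ij(s) − F_ij(h)|` over all `d0 x 16`
  cells.  A true metric (non-negativity, symmetry, triangle
  inequality), verified by property tests.  Its maximum possible value
  is `2 d0` (disjoint supports in every row).
* cosine `d2(s, h) = 1 − cos(F̂(s), F̂(h))`.  Scale-invariant and
  bounded in [0, 1] for non-negative vectors; it is **not** a metric
  (no triangle inequality) and is tested only for symmetry, range and
  the zero-iff-parallel property.

Accumulation order is fixed (rows `d = 1..d0`, then the Ω columns), so
repeated runs produce bit-identical output.

## Bundled benchmark data

The package ships the classic 11-species benchmark: the exon-1 coding
sequences of the beta-globin gene for Human, Chimpanzee, Gorilla,
Lemur, Rat, Mouse, Rabbit, Goat, Bovine, Opossum and Gallus (lengths
86–105 nt; species order is fixed and used for all tabular output).
Here `d0 = min floor(n/4) = floor(86/4) = 21`, so each species is a
`21 x 16` matrix or a 336-dimensional vector.  The sequences follow the
catalogued record lengths; in particular the Mouse record is the 93-nt
sequence consistent with its declared length (a widely circulated
rendering of this dataset duplicates one T near the start, which
perturbs every Mouse distance).

### Known limitation: the Gorilla record

The bundled Gorilla record — identical to the Human coding sequence
plus one trailing G, as circulated with this dataset — yields
`d1(Human, Gorilla) = 0.4602` and `d2 = 0.0008`, i.e. Human and Gorilla
are by far the closest pair.  The historical reference tables for this
benchmark instead report `2.4026` / `0.0074` for that pair (and
correspondingly different values in the rest of the Gorilla column),
which cannot be produced from the circulated Gorilla sequence: the
remaining 45 of the 55 pairwise values reproduce to within 5e-5 on both
measures, while no plausible variant of the Gorilla record (searched
over substitutions, indels, and common parsing artifacts) reproduces
its column.  The reference Gorilla column appears to derive from an
input that was never published.  The package keeps the circulated
sequence and reports what it computes; the acceptance suite marks the
ten Gorilla cells of each table as known failures rather than adjusting
data toward the reference values.

## Downstream summaries

* **Relative similarity.** One species (Human) is chosen as reference
  and one pair (Human–Gorilla) as the unit: every other species x is
  reported as `d(Human, x) / d(Human, Gorilla)` for each measure.  Only
  the ratio construction is provided; it requires a non-zero reference
  distance.
* **PCA.**  The 11 flattened 336-dimensional vectors are mean-centred
  and decomposed by SVD (covariance PCA).  No per-feature
  standardisation is applied: all 336 features are frequencies on a
  common scale, so the covariance convention is the natural one — and
  on the bundled set it places 48% of the total variance on the first
  two components (28.9% + 19.1%), confirming the choice.  Each
  component's sign is fixed by making its largest-magnitude loading
  positive, so projections are reproducible across runs and input
  orderings (coordinates are order-invariant up to this sign rule).
  PCA requires at least two distinct vectors; identical replicates
  (zero total variance) are rejected.

## Numerical and interface choices

* Frequencies and distances are computed in float64; printed precision
  (default 4 decimals) is formatting only.
* Validation is strict by default: any character outside A/C/G/T is an
  error naming the record and position.  An opt-in permissive mode
  keeps ambiguity codes (N, IUPAC letters) and drops every pair that
  touches one from both the numerator and the denominator, so
  frequencies still sum to 1; `n_pairs` records the retained count.
  Lowercase input is silently uppercased — the only silent
  normalisation.
* Sequences shorter than 4 nt are rejected (no valid separation exists
  under the depth cap); `d >= n` is rejected (no pairs exist).
* The CLI is deterministic and seed-free; usage errors exit 2, data
  errors exit 1, and failed runs do not leave partial output files.

## What the tests do and do not show

Unit and property tests cover: brute-force agreement of the vectorised
counter with a position-by-position scan over random sequences; count
conservation (`Σ counts = n − d`) and simplex rows; the metric axioms
for `d1` and the range/scale properties of `d2`; depth-rule edge
cases; FASTA round-tripping; and rank-level claims on the benchmark
(closest primate/bovid pairs, Gallus and Opossum as outliers, Spearman
agreement > 0.9 between the two measures' rankings).  The benchmark
checks establish agreement with the historical reference values at
4-decimal precision for every cell not affected by the Gorilla record
issue above.  All of this concerns short coding sequences (~100 nt);
the descriptor itself runs in `O(n * d0)` and applies unchanged to long
sequences, but no claim about its discriminative power on genomic-scale
or highly repetitive inputs is tested here.
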
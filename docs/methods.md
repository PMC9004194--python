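# Methods

## The density model

TE density treats a gene as a single inclusive interval [g₀, g₁] — from
the first-exon start to the last-exon stop — and asks what fraction of
base pairs a TE grouping occupies in three places relative to that
interval: a flank window left of g₀, the gene body itself ("intragenic",
covering introns and exons alike), and a flank window right of g₁.
Internally all coordinates are 0-based and inclusive on both ends, so
lengths are `stop − start + 1`; both input dialects (GFF3 and the
cleaned-tsv exchange format) carry 1-based inclusive coordinates on disk
and are shifted by −1 on read.

For a window length *w*, the left window is `[max(g₀−1−w, 0), g₀−1]` and
the right window `[g₁+1, g₁+1+w]`. Both span *w*+1 base pairs because the
window bounds sit one base off the gene edge; flank densities are
accordingly normalized by *w*+1, and a TE tiling the whole window gives
exactly 1.0. This off-by-one is a deliberate, tested property of the
model, not an artifact. Intragenic overlap uses the gene bounds and is
normalized by the gene length; it is independent of *w* and is replicated
across the window axis of the output tensor so every (window, gene) cell
is addressable uniformly.

Two boundary choices: left windows are clipped at position 0 (a gene at
g₀ = 0 has an empty left window and zero left density), while right
windows are *not* clipped at the end of the pseudomolecule — sequence
length is not an input to the model, and the denominator stays *w*+1
regardless. Intragenic overlap uses intersection bounds
(`b₀ = max(g₀, t₀)`, `b₁ = min(g₁, t₁)`): this is the only semantics
consistent with normalizing by gene length and with densities bounded by
1.

## Annotation revision

Real TE annotations contain overlapping elements — nested insertions and
annotation-software artifacts. Summing per-TE overlaps would count shared
bases twice and push densities past 1, so the annotation is revised
before any density computation: within every (pseudomolecule, grouping,
label) subset, overlapping intervals are merged into their union. The
merge runs three independent passes — per order, per superfamily, and
once over all TEs to synthesize the pooled `Total_TE_Density` grouping —
so each input TE contributes to at most one merged interval per level.

The merge itself is a sort-by-start linear sweep. Touching but
non-overlapping intervals (`stop + 1 == next start`) are *not* merged:
the per-base union, and hence every density, is identical either way, and
keeping them separate makes merging coincide exactly with interval-union
semantics (a property the tests check exhaustively with per-base masks).
TE strand is ignored throughout; the model never conditions on it.
Because revision depends only on the TE annotation, the result is cached
to disk (cleaned-tsv with a `Revision_Level` column) with a SHA-256
digest of the source file to detect staleness, so re-running with
different windows skips the merge.

## Computation and storage

Densities for one pseudomolecule form a float64 tensor of shape
`|identities| × |windows| × |genes| × 3`, direction axis fixed as (left,
intra, right). The identity axis is the sorted label set of the level
with `Total_TE_Density` appended last, and is fixed genome-wide so the
tensors of different pseudomolecules align. Overlap sums are vectorized
with numpy over the (gene × interval) grid per identity and window.
Pseudomolecules are independent and can be computed in a process pool;
results are deterministic and byte-identical for any worker count (HDF5
dataset time-tracking is disabled so stores are reproducible at the byte
level).

Each pseudomolecule's order and superfamily tensors are stored together
in one HDF5 file, `{genome}_{pseudomolecule}.h5`, with UTF-8 label
vectors and `GENOME_ID` / `PSEUDOMOLECULE` / `SWAPPED` attributes.
Because annotations list start < stop regardless of strand, the computed
"left" flank of an antisense gene is biologically downstream; the
`DensityData` accessor swaps the left/right slices of antisense genes
once at initialization (an involution, verified by test), leaving intra
slices and the on-disk file untouched. `SWAPPED` stays false on disk and
guards a swapped view from being re-persisted.

## Default parameters

* **Windows**: 500 bp to 10 kb in 500 bp steps (20 windows). This grid
  covers the regulatory-distance range over which TE effects on gene
  expression are typically examined; the CLI accepts `first,last,step`
  or an explicit list.
* **Percentile rule**: linear interpolation between order statistics
  (numpy's default), with "within the percentile" meaning ρ ≥ cutoff
  inclusive. Other order-statistic conventions change the cutoff by at
  most one gene's worth of density mass.
* **Binning**: width 0.1 over [0, 1]; every bin half-open `[a, b)` except
  the last, closed at 1.0. Bin edges are computed as `arange(n+1)/n` so
  decimal boundaries compare exactly against decimal inputs. The
  expression cutoff (default use: 0.1 TPM) removes lowly expressed genes
  before binning; expression units are opaque scalars here.
* **Syntelog differences**: ρ_A − ρ_B with genome A first; pairs are
  pre-filtered to E ≤ 0.05 by the loader. Zero-difference pairs are
  tallied separately from the nonzero set.
* **Strand symbols**: `+` → sense, `-` → antisense; `.` or missing is
  treated as sense with a logged warning.
* **TE classification**: `ORDER/SUPERFAMILY` split on the first slash; a
  bare label is an order with `Unknown_Superfam`; absent classifications
  get `Unknown_Order`/`Unknown_Superfam` sentinels. Rename/drop rules
  (YAML or TSV) let users reorganize groupings, e.g. renaming
  `EnSpm_Cacta` to `CACTA` or splitting Penelope elements out of LINE
  into their own PLE order.

## The synthetic-data generator and the oracle

The generator draws gene and TE annotations on 100 kb pseudomolecules
(default: 5 genes of 0.5–3 kb, 20 TEs of 0.1–2 kb, four orders with
nested superfamilies, half the genes antisense). Its overlap knobs are
structural: with probability `te_te_overlap_prob` a TE is placed inside a
previously placed TE's span *and inherits its identity*, guaranteeing
mergeable same-grouping overlaps; `te_gene_overlap_prob` forces TEs into
gene bodies; one gene per pseudomolecule may start at position 0 to
exercise the left-window clip. The same seed always yields byte-identical
files.

The generator emulates the *geometry* real pipelines must handle —
nesting, boundary straddling, identity sparsity — not TE biology: length
distributions, insertion-site preference and family structure are
unmodeled. Passing tests therefore demonstrate the correctness of the
interval arithmetic, merging, storage and reporting on arbitrary
annotation geometry; they say nothing about the quality of any particular
genome's TE annotation, which the method takes as given.

The test oracle recomputes every density from an explicit boolean
occupancy vector per identity (per-base union over matching TEs), sharing
no code with the revision or overlap modules — union semantics make
revision unnecessary on the oracle side, so one comparison checks
revision, overlap, summation and normalization together. The acceptance
suite runs 100 seeded random genomes (≤100 kb, 3–10 genes, 5–50 TEs, 2–4
orders, windows {100, 500, 1000}) and requires every cell to agree within
1e-12; these sizes keep the whole suite under a few seconds while the
mask oracle stays exact.

## Numerical choices and degenerate inputs

Densities are exact rational numbers representable as double-precision
quotients; the pipeline and the oracle compute them identically, so the
suite's 1e-12 tolerance is slack, not a fudge. Ranking ties in the
per-gene report are broken alphabetically. An identity absent from a
pseudomolecule yields an all-zero slice; a gene on a pseudomolecule with
no TEs yields all-zero densities with a warning when computed directly,
while whole-genome processing requires the gene and TE annotations to
agree on the pseudomolecule name set and fails loudly otherwise (a
mismatch there is almost always a naming error, not biology). An empty TE
annotation is rejected — there is nothing to compute. Overlap sums
exceeding their window span raise an internal-consistency error; with
revised input this path is unreachable and exists as a guard against
unmerged input reaching the normalizer.

## Known limitations

* Family-level groupings are not computed (order, superfamily and total
  only), and merged intervals carry only their grouping label, not the
  names of the TEs that produced them.
* A gene is one interval; intronic versus exonic TE placement is not
  distinguished.
* Right windows extending past the assembled sequence are counted as
  TE-free space rather than truncated; genes near pseudomolecule ends
  therefore have conservative right densities.
* Short-TE versus long-TE composition is invisible in the metric: several
  SINEs and one LTR element can produce the same density.
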
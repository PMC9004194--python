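# tedensity

Quantify transposable-element (TE) presence around every gene in a genome.

TEs shape gene regulation, genome architecture and phenotypic variation,
but comparing "how much TE" sits near a gene across genomes and TE types
has lacked a common metric. **TE density** fills that gap: for a gene with
inclusive bounds [g₀, g₁] and a flank window of length *w* base pairs, the
density of a TE grouping is the proportion of window base pairs the
grouping occupies,

```
ρ_left, ρ_right = (Σ O) / (w + 1)        ρ_intra = (Σ O) / (g₁ − g₀ + 1)
```

where each overlap O is the clipped intersection of a TE interval with the
window — left `[max(g₀−1−w, 0), g₀−1]`, right `[g₁+1, g₁+1+w]`, or the
gene body `[g₀, g₁]` (coordinates 0-based inclusive, so a window of length
*w* spans *w*+1 bases). Densities are computed for every gene, every TE
order and superfamily plus a pooled `Total_TE_Density` grouping, and every
window in a user-defined sweep, yielding one
`identity × window × gene × direction` tensor per pseudomolecule
(chromosome). Overlapping same-grouping TEs are merged beforehand so no
base pair is double-counted and every density stays in [0, 1]. Flank
values of antisense genes are swapped at read time so results are always
reported as upstream/downstream.

The package is aimed at genome biologists studying TE–gene relationships:
genome-wide positional trends, TE density versus expression, syntelog
comparisons between related genomes, and per-gene TE summaries.

## Worked example

```python
from tedensity.annotation_io import GeneRecord, TERecord
from tedensity.revision import revise
from tedensity.density_core import WindowSpec, compute_pseudomolecule_density

genes = [GeneRecord("Chr1", "gene1", 5000, 6999, "sense")]
tes = {"Chr1": [
    TERecord("Chr1", 4200, 4899, "LTR", "Copia"),
    TERecord("Chr1", 4700, 5399, "LTR", "Gypsy"),   # overlaps the Copia element
    TERecord("Chr1", 7100, 7400, "TIR", "Mutator"),
]}
tensor = compute_pseudomolecule_density(genes, revise(tes), "order",
                                        WindowSpec((500, 1000)))
for i, label in enumerate(tensor.identity_labels):
    for j, w in enumerate(tensor.windows):
        left, intra, right = tensor.values[i, j, 0]
        print(f"{label:18s} w={w:5d}  left={left:.4f}  intra={intra:.4f}  right={right:.4f}")
```

prints

```
LTR                w=  500  left=1.0000  intra=0.2000  right=0.0000
LTR                w= 1000  left=0.7992  intra=0.2000  right=0.0000
TIR                w=  500  left=0.0000  intra=0.0000  right=0.6008
TIR                w= 1000  left=0.0000  intra=0.0000  right=0.3007
Total_TE_Density   w=  500  left=1.0000  intra=0.2000  right=0.6008
Total_TE_Density   w= 1000  left=0.7992  intra=0.2000  right=0.3007
```

The two overlapping LTR elements are merged into one interval
(4200–5399), which tiles the entire 500 bp left window (`left=1.0000`),
covers 799 of the 1001 bases of the 1 kb window (`0.7992`), and reaches
400 bases into the 2 kb gene (`intra=0.2000`). The TIR element occupies
301 of the 501 right-window bases at w=500 (`0.6008`). `Total_TE_Density`
pools all TEs regardless of identity and is therefore at least as large
as every individual grouping.

## Command line

```sh
tedensity process --genes genes.tsv --tes tes.tsv --genome-id mygenome \
    --windows 500,10000,500 --output-dir stores
tedensity info-gene --store stores/mygenome_Chr1.h5 --gene gene1 --window 1000
tedensity percentile --store stores/mygenome_Chr1.h5 --level order \
    --identity LTR --window 1000 --direction upstream --percentile 99 --out top.tsv
tedensity bins --values density_expression.tsv --expressed-cutoff 0.1 --out bins.tsv
tedensity syntelog-diff --pairs pairs.tsv --store-a A_Chr1.h5 --store-b B_Chr1.h5 \
    --level superfamily --identity Mutator --window 500 --direction upstream --out diff.tsv
```

`process` accepts cleaned-tsv or GFF3 annotations, writes one HDF5 store
per pseudomolecule, and caches the revised (merge-preprocessed) TE
annotation so window changes do not repeat the merge.

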
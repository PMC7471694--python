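# padbench

Padding strategies for one-hot encoded amino acid sequences, and a
benchmark for measuring their effect on protein-classification models.

Deep learning models for protein sequences need fixed-shape input, so a
protein of length *L* over an alphabet of *n* residue symbols is one-hot
encoded into an *(n+1) × T* binary matrix and brought to a common length
*T* by **padding** with an artificial symbol ("0") — usually at the end,
usually without justification.  This package implements seven padding
strategies and quantifies their effect on a hierarchical enzyme
classification task (task 1: enzyme vs non-enzyme; task 2: the enzyme
class, i.e. the first EC digit 1–7).

The padding modes fall into two families:

| family | modes | placement of the pad symbols |
|---|---|---|
| dense  | `post`, `pre`, `mid`, `ext` | one contiguous block (end, start, middle, both ends) |
| sparse | `strf`, `rnd`, `zoom` | spread uniformly, spread randomly, or no pads at all — residues are repeated (`zoom`) |

plus `aug`, the augmentation scheme that represents each sequence by all
seven single-mode paddings at once.

The benchmark trains three architectures (`only_denses`, `1_conv` with one
length-preserving 1D convolution of 64 size-5 filters, and `stack_conv`
with five parallel convolutions) over the factorial grid
architecture × padding × task × fold, then explains the per-label F1
scores with treatment-coded OLS models
(`F1 ~ architecture + enzyme_type + type_padding`, optionally with
interactions), Benjamini–Hochberg adjusted.  The effect of padding on the
learned representation is examined by extracting first-convolution
activations (64 × T per prediction), treating each filter row as a PCA
sample, and regressing PC1 on enzyme type and padding type.

## Worked example

Padding a short sequence to a common length of 12:

```python
from padbench import pad, PaddingConfig

for mode in ("post", "pre", "mid", "ext", "strf", "rnd", "zoom"):
    ps = pad("MKVLAHT", PaddingConfig(T=12, mode=mode, seed=1), source_id="P1")
    print(f"{mode:>5}: {ps.symbols}")
```

prints

```
 post: MKVLAHT00000
  pre: 00000MKVLAHT
  mid: MKVL00000AHT
  ext: 00MKVLAHT000
 strf: MK0V0LA0H0T0
  rnd: M0K0V0L0AH0T
 zoom: MMKKVVLAAHHT
```

Every output has length 12; dense modes keep the five pads in one block,
`strf` spaces them evenly (residue *i* goes to position ⌊*i*·*T*/*L*⌋),
`rnd` scatters them with a per-sequence seeded stream, and `zoom` repeats
residues (output *j* holds input ⌊*j*·*L*/*T*⌋) so no pads are needed.

From the shell, a desk-scale benchmark cell on synthetic data:

```sh
padbench simulate --n 300 --seed 7 --max-length 95 --out demo
padbench train --task 1 --arch 1_conv --padding post --fold 0 \
    --length 100 --epochs 10 --seed 7 --out runs \
    demo/sequences.fasta demo/annotations.tsv
padbench train --task 1 --arch 1_conv --padding rnd --fold 0 \
    --length 100 --epochs 10 --seed 7 --out runs \
    demo/sequences.fasta demo/annotations.tsv
```

prints

```
task1_1_conv_post_fold0: epoch=10 accuracy=0.667 macro_f1=0.631 auc=0.881
task1_1_conv_rnd_fold0: epoch=6 accuracy=0.533 macro_f1=0.348 auc=0.625
```

The synthetic sequences carry class motifs at the N-terminus, so
post-padding (which leaves the motif intact at a stable position) clearly
outperforms rnd-padding, which breaks the motif apart at random positions
— the dense-vs-sparse effect the benchmark is designed to expose.
`epoch` is the 1-based training epoch whose validation accuracy was best;
its weights are the ones evaluated.

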
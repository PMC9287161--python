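# sigcrf

Signal peptide type, cleavage-site and region prediction with a
grammar-constrained multitag conditional random field (CRF) over
per-residue sequence representations.

The package covers the full desk-scale method:

- **grammar** — the 41-state CRF state space: six global classes (no SP
  plus the five SP types Sec/SPI, Sec/SPII, Sec/SPIII, Tat/SPI,
  Tat/SPII), each owning private region and mature states, with a
  transition mask that enforces region order (n → h → c, two-state
  twin-arginine motif, three-state lipobox, undifferentiated SPIII).
- **labeler** — rule-based multitag weak-supervision labels for
  annotated SPs (minimum n/c region lengths, Kyte–Doolittle 7-window
  h-region anchor, RR-motif and lipobox placement, `{n,h}` / `{h,c}`
  ambiguity fills).
- **crf** — log-space forward/backward, Viterbi, the multitag negative
  log likelihood (marginalizing over all paths consistent with the
  per-position label sets), global class probabilities (mean marginal
  mass per class), cleavage-site inference from the last SP state, and
  a hand-derived vector–Jacobian product through forward–backward for
  differentiating losses defined on marginals.
- **encoder** — a pluggable, deterministic desk-scale replacement for a
  large protein language model: windowed residue embeddings plus an
  organism-group token through one tanh layer (D = 64 by default).
- **regularizer** — the composition-divergence term: soft per-region
  amino acid score vectors from the marginals, cosine similarities
  between n/h and h/c, plus the degenerate-run detector (mean predicted
  n-region length collapsing to the minimum of 2).
- **training** — Adamax with a slanted-triangular learning rate,
  analytic gradients (no autodiff framework), restart-on-degeneracy,
  and 3×2 nested cross-validation with ensembled test predictions.
- **partition** — homology-aware dataset partitioning: Needleman–Wunsch
  global identities (BLOSUM62, gap open −11 / extend −1), single-linkage
  clustering, balanced greedy packing into three partitions, and
  iterative removal until no cross-partition pair exceeds the identity
  threshold (0.30 by default).
- **metrics** — detection MCC under two negative-set definitions (MCC1:
  soluble/transmembrane negatives only; MCC2: other SP types included),
  class-conditional CS precision/recall with 0–3 residue tolerance
  windows, the Gorodkin multiclass MCC, and identity-binned performance.
- **regions** — length, mean Kyte–Doolittle hydrophobicity, and pH-7 net
  charge per predicted region, including the +1 amino-group charge for
  the unformylated initiator methionine in Eukarya/Archaea.
- **synth** — a deterministic generator for labeled synthetic datasets
  with the compositional structure of the five SP types plus soluble and
  transmembrane negatives, and mutation-family fixtures for the
  partitioner.

## Command line

All commands run under a single entry point (`sigcrf` or
`python -m sigcrf.cli`):

```bash
sigcrf generate --seed 7 --preset train --out train.fasta
sigcrf label train.fasta --out labels.tsv
sigcrf partition train.fasta --out-prefix parts
sigcrf train train.fasta --out model.json --seed 1
sigcrf crossval parts.part0.fasta parts.part1.fasta parts.part2.fasta \
    --out-prefix cv
sigcrf predict query.fasta --model model.json --out preds.tsv \
    --gff regions.gff3            # --organism defaults to UNKNOWN
sigcrf regions query.fasta --model model.json --out regsum.tsv
sigcrf evaluate preds.tsv truth.fasta --out report.tsv
```

Training data uses a 3-line FASTA dialect: `>id|GROUP|CLASS`, the amino
acid sequence, and a per-residue annotation string over `S/T/L/P/I/M/O`
(the cleavage site is the last SP-tagged position). `predict` accepts
plain FASTA.

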
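# chlamysec

Analysis pipeline for neuropeptide-like precursor processing and the
mating secretome of *Chlamydomonas reinhardtii*.

Unicellular green algae lack neurons, yet their genomes encode the full
enzymatic toolkit of neuropeptide biosynthesis: subtilisin-like
prohormone convertases (PCs), furin-like proteases, carboxypeptidase
B-like (CPB) exopeptidases and peptidylglycine α-amidating monooxygenase
(PAM). `chlamysec` asks, computationally, which secreted *C. reinhardtii*
proteins could be processed by that machinery, and what the mating
secretome looks like when replicate label-free proteomics runs are
merged, filtered and triaged.

## What it computes

**Cleavage/amidation motif grammar.** On each signal-peptide-bearing,
TM-helix-free protein, the scanner finds

- PC sites `(K/R)Xₙ(K/R)↓` with n ∈ {0, 2, 4, 6} (a restricted
  {0, 2} preset is available), cleaving after the second basic residue;
- furin sites `RX(K/R)R↓`;
- amidation motifs `G(K/R)(K/R)`, `(K/R)XₙG(K/R)` (n ∈ {1, 3}) and
  `RG(K/R)R`, plus C-terminal `–Gly` / `–Gly–(K/R)ₙ` endings that can be
  amidated without endoproteolysis;
- NeuroPred-style "known motifs" (user-replaceable pattern table over
  {K, R, X}, with configurable exclusions such as RK, KXXK, KXXR).

Products are enumerated by cutting the mature chain at every predicted
site, trimming C-terminal Lys/Arg (CPB step), and converting a remaining
C-terminal Gly into an α-amide (PAM step: `…X–G → …X–amide`).

**Secretome merge.** Six per-sample spectral-count tables (two datasets
of three samples) are scaled to a common total, merged by protein,
filtered by presence in ≥ 4 of 6 samples, summarized as mean ± SEM
(absent samples contribute 0), ranked, and triaged for signal-peptide
content (localization class SP, or O/NA with a SignalP-style call).

**Topology classification.** Signal + no TM helix → secreted; signal +
helix → Type I; helix without signal → Type II; neither → other.

**Gel-slice cleavage calls.** Tryptic-peptide evidence binned into
SDS-PAGE mass slices decides whether a protein was recovered intact or
as stable proteolytic fragments, and whether fragments are N-terminal,
C-terminal or internal.

**Synthetic data.** Ground-truthed generators for all of the above
(planted motifs, presence patterns with overdispersed counts, planted
gel fragments), so every stage is testable without downloads.

## Worked example

```python
from chlamysec import ProteinRecord, MotifConfig, find_pc_sites, find_furin_sites
from chlamysec.peptide_products import enumerate_products

seq = "MKWVLALLAVFSAEGKRSFLDARQKRTTNQG"   # signal peptide = residues 1-13
rec = ProteinRecord("demo1", seq)
cfg = MotifConfig()

for s in find_pc_sites(seq, cfg, "demo1"):
    print(s.motif_text, s.start, s.end, s.cleavage_after)
for p in enumerate_products(rec, signal_end=13, config=cfg):
    print(p.sequence, p.trimmed_basics, p.amidated, p.amide_residue)
```

prints

```
KR 16 17 17
KRSFLDAR 16 23 23
RQKR 23 26 26
KR 25 26 26
EGKR 2 True E
SFLDAR 1 False None
QKR 2 False None
TTNQG 0 True Q
```

The mature chain `EGKRSFLDARQKRTTNQG` carries a dibasic KR site (cut
after residue 17), an overlapping spaced pair, and a furin site RQKR
(all cuts after residue 26 collapse to one). The first product `EGKR`
is trimmed to `EG` and amidated, leaving Glu-amide; the C-terminal
product `TTNQG` ends in glycine and is a direct PAM substrate, leaving
Gln-amide.

The same stages are available from the shell:

```sh
chlamysec simulate --seed 3 --out fixtures/
chlamysec scan     --fasta fixtures/proteome.fasta \
                   --signal fixtures/signal.tsv --topology fixtures/topology.tsv \
                   --out out/scan
chlamysec topology --signal sig.tsv --topology tm.tsv --out out/topo
```

Classifying the packaged annotation table of the 21 S8
(subtilisin-domain) proteins of the *C. reinhardtii* genome:

```python
from chlamysec import load_s8_reference_annotations, topology_census
from chlamysec.topology_classifier import classify_maps

census = topology_census(classify_maps(*load_s8_reference_annotations()))
# {'secreted': 7, 'type_I': 1, 'type_II': 6, 'other': 7}
```

Seven of the 21 are soluble secreted candidates, one is a Type I
membrane protein (C-terminal anchor downstream of a cleaved signal),
six are Type II (signal-anchor helix, no cleavable signal) and seven
carry neither feature.

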
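# pednet

Plant pedigrees are not family trees. The named entities are near-homozygous
inbred lines that persist as seed for decades, so century-old founders cross
directly into modern material, one line can serve as both parents of a cross
(selfing), and heavily used parents feed dozens of children. The result is a
dense directed acyclic multigraph — a **pedigree net** — that breeders record
as terse notation strings and that standard family-tree tools cannot draw or
audit.

`pednet` is a library and command-line toolkit for working with such nets,
aimed at plant breeders, geneticists and the bioinformaticians who curate
their germplasm collections:

* **Notation parsing** — Purdy strings (`A/B//C/3/D`: separators of
  increasing order mark successive crosses), Lamacraft–Finlay strings
  (`((A * B) * C) * D`), and the mixed bracket/`×` records found in old
  books, parsed to binary cross trees and *atomised* to elementary
  `(child, parent_1, parent_2)` records.
* **The net itself** — construction with validation (cycles, duplicate
  definitions), ancestor/descendant traversal, generation assignment by
  longest path, usage statistics, principal/flanking/terminal line
  classification, wildcard search, local views, selection-based edge
  filtering.
* **Layered drawing** — a Sugiyama-style layout (generations top-down, dummy
  vertices for multi-generation edges, barycenter crossing reduction)
  rendered to SVG, GraphViz dot or a JSON graph document.
* **Phenotype overlays** — qualitative hue scales for nominal DUS-style
  characters, strictly monotone saturation ramps for ordinal ones, merged
  multi-trait classes, and node sizing by parental usage.
* **Genotype QC** — allele-sharing (identity-by-state) similarity with
  cutoff queries, Mendelian trio checking under the union rule appropriate
  for inbred offspring, genotype matching for unknown samples, and
  second-parent inference.
* **Simulation** — synthetic breeding programmes with controlled selfing,
  old-parent reuse, residual heterozygosity and injectable genotyping
  errors, with full ground truth for every corruption.

## Worked example

The barley variety **Quench** is a cross between Sebastian and Drum. From
Python:

```python
from pednet import (ParentChildRecord, build_net, classify_lines,
                    layered_layout, serialize_purdy)

net = build_net([ParentChildRecord("Quench", "Sebastian", "Drum")])
net.parents("Quench")        # ('Sebastian', 'Drum')
serialize_purdy(net, "Quench")   # 'Sebastian/Drum'
layered_layout(net).positions
# {'Sebastian': (0.0, 0), 'Drum': (30.0, 0), 'Quench': (0.0, 1)}
classify_lines(net)
# {'Drum': 'flanking', 'Quench': 'terminal', 'Sebastian': 'flanking'}
```

Both parents sit on layer 0 and Quench one generation below; Quench has no
progeny (`terminal`), while each founder has been used once (`flanking`).

From the shell, simulate a small programme with three planted genotyping
errors and audit it:

```sh
$ pednet simulate --founders 10 --crosses 30 --markers 200 \
      --errors 3 --seed 42 -o sim
40 lines, 40 genotyped, 200 markers, 3 injected errors

$ pednet check sim/pedigree.csv sim/genotypes.tsv -o report.tsv
3 violations / 30 trios tested (6000 loci; 3 trio, 0 single-parent)

$ head -2 report.tsv
child   marker  child_call      p1_call p2_call rule
C013    M00008  AA      CC      CC      trio
```

All three planted errors are recovered: line C013 carries `AA` at marker
M00008 although both parents are `CC`, so the call cannot have been
inherited. `check` exits 1 when violations are found, which makes it easy
to gate data loads in scripts. Other subcommands: `parse`, `render`,
`local`, `similarity`, `match`, `infer-parent`, `search`,
`degree-summary`, `export`.

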
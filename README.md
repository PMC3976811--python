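# wrkytools

Genome-wide analysis of the WRKY transcription-factor family, built as a
reusable pipeline.  WRKY proteins are one of the largest plant
transcription-factor families; each carries a ~60-residue DNA-binding WRKY
domain — the near-invariant heptapeptide **WRKYGQK** followed by a
zinc-finger motif — and binds the W-box (TTGAC[T/C]) element.  The package
implements every stage of a family survey for the model legume
*Lotus japonicus*:

* **Domain grammar scanning** — heptapeptide variants
  `W[RKLSV][RKC]YG[QYELK]K` plus the two zinc-finger grammars
  C–X₄₋₅–C–X₂₂₋₂₃–H–X–H (C2H2) and C–X₅₋₈–C–X₂₅₋₂₈–H–X₁₋₂–C (C2HC);
  classification into group I (two domains), II (one domain, C2H2) and
  III (one domain, C2HC), with group II subgroups IIa–IIe/IIx assigned by
  nearest labelled reference domain under alignment p-distance.
* **Candidate filtering and pseudogene flagging** — domains shorter than
  2/3 of the nominal length are dropped; premature in-frame stop codons
  and frameshifts (CDS length ≢ 0 mod 3) are flagged from the CDS.
* **Genome organization** — duplicate gene pairs by the 70/70 rule
  (aligned nucleotide coverage of the longer CDS > 70% *and* amino-acid
  identity > 70%; tandem if on one chromosome, else segmental) and gene
  clusters as ≥ 2 genes chaining within 200 kb.
* **Gene structure** — intron phases from exon coordinates and the two
  conserved WRKY-domain introns: R-type (phase 2, splitting an R codon
  before the zinc finger) and V-type (phase 0, immediately before the
  codon at second-C + 6 of a C2H2 finger).
* **Phylogenetics** — p/Poisson distances with pairwise gap deletion,
  Saitou–Nei Neighbor-Joining, bootstrap supports on the full-data tree's
  bipartitions, and a basic progressive aligner (UPGMA guide tree +
  profile NW).
* **Selection analysis** — GY94 codon models with site-model mixtures
  M0 / M3 / M7 / M8, maximum-likelihood fitting (Felsenstein pruning over
  61 codon states, F3x4 frequencies), likelihood-ratio tests
  (M0 vs M3, df 4; M7 vs M8, df 2) against χ², and naive-empirical-Bayes
  identification of sites with ω = dN/dS > 1.
* **Synthetic data** — genomes with planted domains, pseudogenes, clusters,
  duplicate pairs and R-/V-type introns (full truth tables), and GY94
  codon-alignment simulation, so every stage is testable with known ground
  truth and no downloads.

A packaged curated gene table (71 entries: name, group, chromosome,
coordinate, pseudogene flag) drives the genomic-organization reports
without any sequence input.

## Worked example

```python
>>> from wrkytools.sequence_io import load_gene_table
>>> from wrkytools.pipeline import summarize_family
>>> from wrkytools.genome_organization import detect_clusters
>>> table = load_gene_table()
>>> summarize_family([r.group for r in table.classified()])
{'I': 12, 'IIa': 5, 'IIb': 8, 'IIc': 13, 'IId': 5, 'IIe': 9, 'IIx': 2,
 'III': 7, 'other': 0, 'II': 42, 'total': 61}
>>> for c in detect_clusters(table.loci()):
...     print(c.chromosome, c.member_ids, c.span_bp)
1 ['LjWRKY2', 'LjWRKY3'] 32212
2 ['LjWRKY17', 'LjWRKY19', 'LjWRKY20'] 157942
4 ['LjWRKY34', 'LjWRKY35'] 129106
5 ['LjWRKY40', 'LjWRKY41'] 78283
```

Of the 71 curated entries, 61 classify into groups I/II/III (12/42/7, with
13 in subgroup IIc) and 9 carry pseudogene lesions.  48 genes map to
chromosomes 1–6 (14 on chr1, 8 on chr2, 13 on chr4).  Applying the strict
200-kb chaining rule to the table's coordinates yields four clusters over
nine genes — one per chromosome 1, 2, 4 and 5 and none on 3 or 6 — with the
pair LjWRKY34/LjWRKY35 on chromosome 4 also being the family's single
tandem duplication.

The command-line interface exposes the same stages
(`wrkytools scan|organize|structure|phylo|selection|simulate|motifs|fixture|report`):

```sh
wrkytools report --mode synthetic --outdir out --seed 3 --bootstrap 100
wrkytools organize --window 200000
```

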
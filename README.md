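# misrank

Quantifying the association between a query gene set and many disease-gene
classes on a weighted protein–protein interaction (PPI) network.

Motivating application: obesity is genetically entangled with other diseases,
but which disease classes share the most molecular ground with it?  Given the
~342 curated obesity genes that map onto the STRING human PPI network and the
22 OMIM disease classes (bone, cancer, endocrine, nutritional, psychiatric,
…), `misrank` scores every disease gene by the strength of its best PPI link
into the obesity set, calibrates that score with a permutation test, and
ranks the disease classes by how strongly their gene complements concentrate
near p = 0.  The same machinery applies to any query set / class catalog /
weighted network triple in the STRING `protein.links` dialect.

## Method

The network carries an integer confidence score `S(p1, p2)` per undirected
edge (STRING combined scores, 150–999).  For a disease gene *g* and query set
*Q* (guilt-by-association: interacting proteins tend to share function):

* **Maximum interaction score** — `MIS(g) = max{ S(g, g′) : g′ ∈ Q, g′ ≠ g }`,
  0 if no edge links *g* to *Q*.
* **Permutation p-value** — draw `n` random node sets `D_1 … D_n` of size
  `|Q|` uniformly from the network (default `n = 1000`), compute
  `MIS_i(g) = max{ S(g, g′) : g′ ∈ D_i }`, and set
  `p(g) = Λ/n` with `Λ = #{ i : MIS_i(g) > MIS(g) }` (strictly greater).
  A low p means *g*'s link into *Q* is stronger than its links into almost
  every random set of equal size, i.e. not explained by *g* being a hub.
* **Proportion–threshold (PT) curve and AUC** — for one class with p-values
  `p_1 … p_m`, the PT curve maps a threshold *t* to the fraction of genes with
  `p < t` (the strict empirical CDF).  Its exact area,
  `AUC = mean_j(1 − p_j) ∈ [0, 1]`, summarizes the class: 1 means every gene
  is maximally associated with the query set, ~0.5 is the null expectation.
  Classes are ranked by AUC.

A synthetic-study generator (Erdős–Rényi background + classes whose genes
receive high-score edges to the query set with a known *planting strength*)
provides ground-truthed fixtures for calibration and recovery benchmarks.

## Worked example

Generate a synthetic study with a known answer, run the full pipeline, and
rank the classes:

```sh
misrank simulate --n-proteins 300 --edge-probability 0.1 --query-size 30 \
    --classes "strong-signal:20:0.9,weak-signal:20:0.4,unrelated:20:0.0" \
    --seed 1 --out-dir demo
misrank run --network demo/network.links.txt --query-set demo/query_genes.txt \
    --classes demo/disease_classes.tsv --n-perm 1000 --seed 1 --out-dir demo_out
```

which prints

```
  1  strong-signal                  AUC=0.9305 (n=20)
  2  weak-signal                    AUC=0.6366 (n=20)
  3  unrelated                      AUC=0.5005 (n=20)
```

The three classes were planted with strengths 0.9 / 0.4 / 0.0 — the ranking
recovers the truth, the unrelated class sits at the null AUC of ~0.5, and the
AUC ordering tracks planting strength.  `demo_out/` holds the result tables:
`per_gene.tsv` (every gene's MIS, Λ and p-value), `class_summary.tsv`
(ranked AUC per class, with the input→filtered gene-count audit),
`pt_curves.tsv` (curve points for plotting), `per_gene_significant.tsv`
(the p < 0.05 presentation cut, here 23 genes: 15 from the strongly planted
class, 8 from the weak one), and `run_metadata.json` (seed, counts,
provenance).
For example the head of `per_gene_significant.tsv`:

```
gene_id	class	mis	lambda	p_value
P000030	strong-signal	982	0	0
P000032	strong-signal	991	0	0
P000033	strong-signal	993	0	0
```

`misrank score` runs a single gene set, and `misrank rank` re-ranks from
saved per-gene tables.  `misrank run --config run.yaml` reads the same
options from YAML, with flags overriding.

At full scale (STRING v10 human links, the obesity query set, the 22-class
OMIM catalog — external downloads), `scripts/full_scale_study.py` reruns the
original analysis; the expected outcome there is the Nutritional > Endocrine
> Psychiatric > Bone head of the ranking with Nutritional's AUC ≈ 0.962 and,
e.g., UCP1 at MIS 969 against the obesity set.

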
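# lnspf — essential-protein ranking by multifeature fusion and linear neighborhood similarity

Essential (key) proteins are those whose deletion is lethal to the organism;
in protein–protein interaction (PPI) networks they tend to sit in densely
interconnected clusters, to be conserved across species, and to share
subcellular compartments and expression dynamics with their partners.
`lnspf` ranks the proteins of a PPI network by predicted essentiality by
fusing four per-protein features and propagating the fused scores in two
iterative loops.

## Method

Given the network *G = (V, E)* with adjacency *A*, one-hop neighborhoods
*NG(p)* and the literal two-hop union *THNG(p) = ∪<sub>k∈NG(p)</sub> NG(k)*:

**Features.** Two topological scores sum pairwise neighborhood overlaps over
a protein's partners,

> TP1(i) = Σ<sub>j∈NG(i)</sub> |NG(i)∩NG(j)| / |NG(i)|,  TP2(i) = Σ<sub>j∈NG(i)</sub> |THNG(i)∩NG(j)| / |THNG(i)|,

and two functional scores use subcellular localization sets *Sub(p)* and
orthology (conservation) scores *os(p)*:

> FP1(i) = Σ<sub>j∈NG(i)</sub> |Sub(i)∩Sub(j)|² / (|Sub(i)|·|Sub(j)|) / (|NG(i)|+1),  FP2(i) = os(i) / max<sub>j</sub> os(j).

**Entropy-weight fusion.** The N×4 feature matrix Z is column-normalized;
each feature's Shannon entropy e<sub>j</sub> = −Σ<sub>i</sub> z<sub>ij</sub> ln z<sub>ij</sub> / ln N measures
how uninformative it is, and the fused score is
CScore(i) = Σ<sub>j</sub> w<sub>j</sub> z<sub>ij</sub> with w<sub>j</sub> ∝ (1 − e<sub>j</sub>).

**Two propagation loops.** A dense coupling matrix
H<sub>ij</sub> = min(CScore(i), CScore(j)) / Σ<sub>l</sub> CScore(l) (diagonal: CScore(i)/Σ) spreads
the conservation prior Y⁰ = FP2 via Y<sup>t+1</sup> = αHY<sup>t</sup> + (1−α)Y⁰ until the
update norm falls below δ. The converged Y^Final is then refined over the
**linear neighborhood similarity** matrix S built from gene-expression
profiles: each protein is reconstructed as a convex combination of its
interaction partners' profiles by the simplex-constrained quadratic program
min s<sup>T</sup>(Gⁱ + μI)s, and T<sup>σ+1</sup> = βST<sup>σ</sup> + (1−β)T⁰ (T⁰ = Y^Final) yields the
final ranking score T^Final. Defaults: α = 0.6, β = 0.4, δ = 10⁻⁶, μ = 1.

## Worked example

Real datasets (interaction databases, orthology tables, localization
annotations) are not bundled; the built-in simulator generates benchmarks
with the same structure — a preferential-attachment network with a planted
essential subset that is better connected, more conserved, co-localized and
co-expressed:

```bash
lnspf simulate --seed 7 --out demo/data
lnspf run --ppi demo/data/ppi.tsv --expression demo/data/expression.tsv \
          --subcellular demo/data/subcellular.tsv --homology demo/data/homology.tsv \
          --out demo/run
lnspf evaluate --ranking demo/run/ranking.tsv --labels demo/data/labels.txt --out demo/eval
```

which prints

```
ranked 300 proteins -> demo/run/ranking.tsv
AUC = 0.8687 -> demo/eval/report.json
```

`ranking.tsv` lists every protein with its final score and the intermediate
stage scores:

```
rank  protein  t_final     y_final     cscore
1     P0067    1.09951426  0.50326260  0.00484985
2     P0264    1.03732541  0.46644494  0.00481282
3     P0128    0.97141625  0.36158002  0.00520402
```

and `demo/eval/topk.tsv` counts planted essentials among the top-K% ranked
proteins — e.g. all 3 proteins of the top 1% slice, and 25 of the 30
proteins in the top 10% slice, are among the 60 planted essentials:

```
top_k_percent  essential_count
1   3
5   15
10  25
```

An AUC of 0.87 means a randomly chosen essential protein outranks a randomly
chosen non-essential one 87% of the time. The same pipeline is available as
a scikit-learn-style estimator:

```python
from lnspf import LNSPF, SyntheticSpec, generate
net, expr, sub, os_map, labels = generate(SyntheticSpec(seed=7))
model = LNSPF(alpha=0.6, beta=0.4).fit(net, expr, sub, os_map)
model.ranking_[:3]          # [(protein, T_final), ...]
```

`lnspf sweep --param beta --values 0.1,...,0.9` grids a propagation
parameter and tabulates top-K% counts per value.

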
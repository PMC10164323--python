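# owsum

Interpretable odor prediction from molecular structure.

`owsum` predicts a molecule's odor descriptor (floral, fruity, sickening,
…) from the structural patterns it contains, using a linear classifier
whose every term can be read off and ranked. It is aimed at flavor and
fragrance researchers who need not just a predicted label but an
explanation — *which* substructures push a molecule toward *which* odor —
and at anyone with a multilabel classification problem over binary
features who wants a transparent baseline.

## The model

Molecules are encoded as SMILES, features as SMARTS substructure patterns.
A feature either occurs in a molecule or it does not; multiplicities are
deliberately ignored so small fragments are not overrepresented. For a
feature $F_j$ and class $C_i$, training counts give the **weight**

$$G_{j,i} = \Pr(F_j \mid C_i)$$

— the fraction of class members containing the feature. A weighting
factor $a_{i,j}$ turns the weight into the **influence**

$$I_{i,j} = a_{i,j} \cdot G_{j,i},$$

with $a = 1$ (same-weighted) or $a = \text{tf-idf}_{i,j}$
(tf-idf-weighted), where

$$\text{tf-idf}_{i,j} = \frac{\#(F_j, C_i)}{\mathrm{len}(C_i)}\cdot
\log\frac{|C|}{\sum_{C_n : F_j \in C_n} 1}.$$

Because occurrence is binary the term-frequency factor equals $G$, so the
tf-idf-weighted influence is $G^2 \cdot \mathrm{idf}$. Features occurring
in every class have idf = 0 and can be dropped (idf feature selection).
An object's score per class is the sum of the influences of its features,

$$S_{i,k} = \sum_{F_j \in O_k} I_{i,j},$$

and the argmax set is the prediction. An object with no usable features,
or whose argmax spans all classes, is *unpredictable*. The per-class
influence tables double as a ranking of which substructures matter for
which odor.

The package also provides the **descriptor overlap** metric
$\#M_{d_1 \cap d_2} / \min(\#M_{d_1}, \#M_{d_2}) \in [0,1]$ for screening
semantically redundant odor labels, the panel-preprocessing pipeline that
turns percent-applicability tables into selective multilabel datasets,
MCS-based SMARTS catalog construction, and the full validation protocol
(five-fold cross-validation, overall/predicted accuracy, and
under-/over-estimated one-vs-rest ROC AUC and MCC for multilabel data).

## Worked example

Four molecules, two odor classes, three SMARTS features (hydroxyl,
benzene ring, carbonyl):

```python
from owsum import toy_fixture, fit, predict, rank_features

f = toy_fixture()            # phenol, ethanol, acetophenone, acetone
model = fit(f.occurrence, f.labels, variant="tfidf_weighted")
print(rank_features(model, "A"))
for p in predict(f.occurrence, model):
    print(p.object_id, p.status, sorted(p.predicted),
          {c: round(s, 4) for c, s in p.scores.items()})
```

prints

```
[('[O&X2&H1]', 0.6931471805599453), ('[C&X3](=[O&X1])[#6]', 0.0)]
M1 predicted ['A'] {'A': 0.6931, 'B': 0.0}
M2 predicted ['A'] {'A': 0.6931, 'B': 0.0}
M3 predicted ['B'] {'A': 0.0, 'B': 0.6931}
M4 predicted ['B'] {'A': 0.0, 'B': 0.6931}
```

The hydroxyl pattern occurs in both class-A molecules and no class-B
molecule, so its weight for A is 1 and its idf is $\ln 2 \approx 0.6931$;
its influence $G^2\,\mathrm{idf} = 0.6931$ is the entire class-A score of
both molecules carrying it. The benzene pattern occurs in both classes
(idf = 0) and is dropped by feature selection.

The same pipeline is scriptable from the shell:

```bash
owsum simulate --n-per-class 10 --seed 7 -o mols.csv --catalog cat.smarts
owsum crossval mols.csv -c cat.smarts --seed 7 -o report.json
owsum fit mols.csv -c cat.smarts -o model.tsv
owsum predict mols.csv -m model.tsv -o predictions.csv
```

Further subcommands: `extract-features` (pairwise-MCS catalog
construction), `match` (occurrence matrices), `overlap`
(descriptor-overlap matrices and chord-diagram edge lists), and
`preprocess` (applicability thresholding, descriptor support and
mean-overlap screens for raw panel tables).

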
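# crpkit

Toolkit for **cysteine-rich-peptide (CRP) fingerprinting** — authenticating
closely related medicinal herbs from the 2–6 kDa peptide-marker window of
MALDI-TOF mass spectra (or, equivalently, from UPLC chromatograms), the
region populated by hyperstable plant CRPs such as defensins, hevein-like
peptides and PA1b-like peptides.

The motivating problem is the two-class case of *Radix Astragali* (RA, roots
of *Astragalus membranaceus*) versus its common substitute *Radix Hedysarum*
(RH, roots of *Hedysarum polybotrys*): RA carries the astratide markers
aM1/bM1, RH the hedytide markers hP1/hP2, and a full-profile fingerprint
plus chemometric classification separates the species. The package is aimed
at analytical chemists and chemometricians who need the complete workflow as
reusable, scriptable pieces.

## What it implements

**Preprocessing.** Correlation optimized warping (COW): both signals are cut
into segments of length *m*; each interior query boundary may move by up to
the slack *t*; the warp maximises Σⱼ r(refⱼ, interp(queryⱼ)) over segments
(Pearson r), solved exactly by dynamic programming. Reference selection (row
with maximal summed correlation), segment/slack tuning by a simplicity +
peak-factor score, SNV ((x−x̄)/s per row), sum-normalisation, blank
subtraction, and column mean centering fitted on calibration rows only.

**Exploration.** PCA by centered SVD with Hotelling's T² and Q-residual
outlier screening (F-distribution and Jackson–Mudholkar limits, conjunctive
flagging at 95%), and Ward hierarchical clustering on squared Euclidean
distances with k- or height-cuts and Newick export.

**Classification.** Kennard-Stone per-class max–min splitting (default 60%
calibration), then five models behind one `fit(X, y)` / `predict(X)`
contract: PLS-DA (0/1-coded response, threshold 0.5), KNN (K = 3 default,
leave-one-out K selection), SIMCA (per-class PCA, residual-variance F-test,
may return `"unassigned"`), CART (unpruned Gini tree) and SVM-DA (linear,
C = 1). Evaluation: venetian-blinds cross-validation, confusion matrices
with sensitivity/specificity/NER/ER under an explicit unassigned-handling
rule, RMSEC/RMSECV/RMSEP, and calibration-curve statistics (LOD = 3.3σ/slope,
LOQ = 10σ/slope, RSD%, spike-recovery accuracy%).

**Marker analytics.** Cysteine-spacing motifs in C-Xn notation, ungapped
pairwise identity, monoisotopic/average masses with disulfide and
S-carbamidomethylation arithmetic, and in-silico trypsin/chymotrypsin
digests with missed cleavages. The five characterised marker sequences ship
as a FASTA fixture.

**Synthetic data.** A seeded generator of two-class fingerprint datasets
(Gaussian marker peaks at the published marker masses, multiplicative and
additive noise, baseline, global shift and smooth warp, triplicates), so
every stage is testable without the deposited raw spectra.

## Worked example

Marker analytics on the bundled sequences:

```sh
$ crpkit markers motif
aM1,6,C-X3-C-X7-C-X4-C-X-C-X9-C
bM1,8,C-X10-C-X8-C-X3-C-X10-C-X4-C-X-C-X-C
hP1,6,C-X3-C-X7-C-X4-C-X-C-X9-C
hP2,8,C-X10-C-X8-C-X3-C-X10-C-X4-C-X-C-X-C
aB1,6,C-X6-C-X7-C-C-X3-C-X10-C

$ crpkit markers identity bM1 hP2
62.2

$ crpkit markers digest hP1
start,end,residues,missed,mass_mono,mass_average
1,21,QGCNGPCTPFEQPPCGIQSCR,0,2220.9173,2222.5069
22,31,CFPEVLFFGR,0,1213.5954,1214.4367
32,37,CSTPSG,0,550.2057,550.5838
```

aM1 and hP1 share one six-cysteine motif (PA1b-like), bM1 and hP2 another
eight-cysteine motif (defensin) at 62.2% identity — same families, different
species, which is exactly why the peak masses discriminate the two herbs.
The 550 Da tryptic fragment is hP1's C-terminal peptide CSTPSG.

Full pipeline on the default synthetic benchmark (38 RH + 49 RA samples in
triplicate, 30935-point 2–6 kDa grid, seed 7):

```sh
$ crpkit run --out runs/demo
samples: 53 calibration / 34 validation
outliers flagged: none

model         CV%    Pred%     ER    NER   Spec   Sens   NA
knn        100.00   100.00   0.00   1.00   1.00   1.00    0
plsda      100.00   100.00   0.00   1.00   1.00   1.00    0
svmda      100.00   100.00   0.00   1.00   1.00   1.00    0
cart       100.00   100.00   0.00   1.00   1.00   1.00    0
simca       13.21    14.71   0.44   0.56   1.00   0.21   29
```

Column meanings: CV% is venetian-blinds accuracy on the 53 calibration
samples, Pred% the accuracy on the 34 held-out samples, and the rates are
computed with RA as the positive class; NA counts SIMCA's unassigned
samples. Distance- and covariance-based models separate the two marker
patterns perfectly; SIMCA's strict residual F-test rejects many warped
in-class samples (see `docs/methods.md` for why class modelling is the
conservative outlier here). Outputs land in `runs/demo/`: aligned and
preprocessed matrices, split indices, PCA scores, T²/Q table with limits, a
Newick dendrogram and `metrics.{json,txt}`.

## Layout

```
src/crpkit/
  io.py            spectra, fingerprint matrices, ASCII/CSV I/O
  simulate.py      synthetic two-class fingerprint generator
  preprocess.py    COW alignment, SNV, centering, normalisation, recipes
  unsupervised.py  PCA + T²/Q screening, Ward HCA
  classify.py      Kennard-Stone, PLS-DA/KNN/SIMCA/CART/SVM-DA
  evaluate.py      CV folds, confusion metrics, method validation
  markers.py       motifs, identity, masses, digests
  pipeline.py      config-driven end-to-end workflow
  cli.py           `crpkit` command-line entry points
  data/            marker FASTA + published validation tables
```
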
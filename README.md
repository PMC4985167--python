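# seqfam

Protein functional-family classification from sequence-derived structural and
physicochemical descriptors — no alignment, no similarity search.

Each protein sequence is encoded as a fixed-length feature vector built from:

- amino-acid composition (20 values);
- composition/transition/distribution (CTD) encodings under a three-class
  partition of the amino acids for each of 12 physicochemical properties
  (21 values per property: 3 C + 3 T + 15 D);
- optional Moreau-Broto autocorrelation of amino-acid indices;
- optional pseudo-amino-acid composition (sequence-order correlation terms).

Family membership is predicted by independent binary models, one per family,
with three interchangeable backends:

- **svm** — soft-margin Gaussian-kernel SVM with per-class misclassification
  costs and Platt sigmoid posterior probabilities;
- **knn** — Euclidean-distance majority vote over the k nearest training
  vectors;
- **pnn** — probabilistic neural network: Bayes rule over Parzen-window
  class-conditional densities.

Datasets for each family are built by a staged protocol: same-named proteins
of different species origin are grouped and distributed round-robin over
train/test/independent partitions; negatives are sampled (3 representatives
per domain family) from domain families that contain no family member; exact
duplicate sequences are removed within and across partitions. Hyperparameters
are tuned on the testing partition, the model is retrained on train+test,
evaluated (SE/SP/PR) on the independent partition, and the final model is
retrained on all data.

A synthetic-family generator produces labelled benchmarks with controllable
composition bias, imbalance and noise, so the full pipeline runs and is
tested without any external database.

## Test

```sh
python -m pytest -q tests/
```

The suite includes brute-force oracle checks for every descriptor and
classifier primitive, property-based invariant tests, and an acceptance
suite (`tests/test_acceptance.py`).

## CLI

```sh
# generate a synthetic benchmark (FASTA + annotation TSVs + manifest)
seqfam simulate --n-pos 60 --n-neg 300 --seed 1 --out-dir bench/

# descriptor extraction: one TSV row per sequence (default 272 columns)
seqfam extract bench/sequences.fasta --out features.tsv

# dataset construction for one family (split manifest TSV)
seqfam build-datasets bench/sequences.fasta \
    --families bench/families.tsv --domains bench/domains.tsv \
    --family-id memberfam --seed 1 --out split.tsv

# train (runs the full staged protocol), then predict and evaluate
seqfam train bench/sequences.fasta \
    --families bench/families.tsv --domains bench/domains.tsv \
    --family-id memberfam --method svm --seed 1 \
    --model-out model.json --report-out report.json
seqfam predict query.fasta model.json --out predictions.tsv
seqfam evaluate bench/sequences.fasta model.json \
    --families bench/families.tsv --out eval.json
```

Descriptor configuration is a JSON file passed via `--config` (enabled
blocks, property list, autocorrelation scales/`max_lag`, PseAAC
`lam`/`w`). Every model archive records a digest of the configuration and
property tables it was trained with; prediction refuses queries featurized
under a different configuration.

The amino-acid class assignments per property and the amino-acid index
scales are packaged as editable TSV tables
(`src/seqfam/data/property_groupings.tsv`, `property_scales.tsv`).

## Notes

- Ambiguous residues (B, Z, X, U, O, gaps) are dropped with a warning by
  default; a strict `reject` policy is available.
- For the worked example, 15 class transitions over 29 adjacent pairs give
  15/29 = 0.517, i.e. 0.52 at 2 decimals.
- Undefined evaluation ratios (e.g. precision with no positive calls) are
  reported as not-applicable (`NA`/`null`), never as 0.
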
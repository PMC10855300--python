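# Hyperparameter grids for nested cross-validation (inner loop, F1-scored).
# Small published-default grids; classifiers absent from this file are tuned
# over their library defaults only (grid of size one).
LR:
  C: [0.01, 0.1, 1.0, 10.0]
SVM:
  kernel: [linear, rbf]
  C: [0.1, 1.0, 10.0, 100.0]
KNN:
  n_neighbors: [3, 5, 7]
DTC:
  max_depth: [3, 5, null]
RF:
  n_estimators: [100]
ETC:
  n_estimators: [100]
GBC:
  n_estimators: [100]
BC:
  n_estimators: [10]
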
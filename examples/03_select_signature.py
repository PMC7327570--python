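"""Sweep nested top-k gene sets with SVM leave-one-out cross-validation and
select the signature at the accuracy peak.

Prints the IFS curve, the selected subset size k*, and the Table-1-style
confusion matrix of the final signature.
"""

from sigsift import (
    ClassifierParams,
    MCFSParams,
    SyntheticConfig,
    generate_dataset,
    ifs_curve,
    loocv_evaluate,
    run_mcfs,
    select_signature,
)

cfg = SyntheticConfig(
    class_sizes=(15, 15, 15, 15), n_genes=120, n_informative=6, effect_size=3.0, seed=11
)
matrix, labels, truth = generate_dataset(cfg)

ranked, _ = run_mcfs(matrix, labels, MCFSParams(m=10, s=120, t=3, seed=11))
curve = ifs_curve(ranked, matrix, labels, ClassifierParams(seed=11), max_k=15, step=1)

print("IFS curve (top-k genes -> LOOCV accuracy):")
for k, acc in curve.points:
    print(f"  k={k:>2}  accuracy={acc:.3f}")

k_star, signature = select_signature(curve, ranked)
accuracy, cm = loocv_evaluate(matrix.loc[signature], labels, ClassifierParams(seed=11))
print(f"\nselected signature: k*={k_star} genes, LOOCV accuracy {accuracy:.3f}")
print(f"planted genes in signature: {len(set(signature) & set(truth.informative_genes))}"
      f" of {len(truth.informative_genes)}")
print("\nconfusion matrix (predicted rows x actual columns):")
print(cm.to_table().to_string())
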
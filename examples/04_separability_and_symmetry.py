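"""Separability diagnostics: J-score, 2-D projections, embedding symmetry.

The J-score is the ratio of between-class to within-class scatter of the
feature matrix; higher means better-separated classes.  The symmetry
report quantifies the mirror arrangement of complementary k-mer vectors
in the principal plane of an embedding table.
"""

from i5hmcvec import (
    FixtureSpec,
    j_score,
    reduce,
    run_fixture_pipeline,
    symmetry_report,
)

spec = FixtureSpec(
    n_chromosomes=2,
    chromosome_length=40_000,
    n_transcripts=24,
    peak_length_range=(200, 800),
    seed=3,
)
result = run_fixture_pipeline(spec, corpus_nt=20_000)
X, y = result.features, result.labels

js = j_score(X, y)
print(f"J-score of the 600-D features: {js.j:.4f} "
      f"(between {js.s_b_trace:.3g} / within {js.s_w_trace:.3g})")

coords = reduce(X, target_dim=2, method="tsne", seed=0)
print(f"t-SNE coordinates: {coords.shape[0]} rows x {coords.shape[1]} dims")
print(f"J-score in the t-SNE plane: {j_score(coords, y).j:.4f}")

report = symmetry_report(result.multik.tables[3])
for relation, score in report.scores.items():
    print(f"{relation} mirror score: {score:+.3f} "
          "(1 = perfect mirror about the first principal axis, 0 = none)")
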
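"""Train k-mer embedding tables on a synthetic genome corpus.

Builds a small genome, cuts it into fragments, trains one skip-gram table
per word length, and shows that co-trained tables give every observed
k-mer a dense vector that neighbours the k-mers it co-occurs with.
"""

import numpy as np

from i5hmcvec import (
    FixtureSpec,
    build_corpus,
    generate_genome,
    train_multi_k,
)

spec = FixtureSpec(n_chromosomes=2, chromosome_length=30_000, seed=0)
genome = generate_genome(spec)
corpus = build_corpus(genome, ["chr1", "chr2"], fragment_length=10_000, max_k=5)
print(f"corpus: {len(corpus)} fragments from {corpus.source_chromosomes}")

multik = train_multi_k(corpus, ks=(3, 4, 5), dim=16, window=3, epochs=2, seed=0)
for k, table in multik.tables.items():
    print(f"k={k}: vocabulary {len(table.vectors)} of {4**k} possible, dim {table.dim}")

# cosine neighbours of one 3-mer
table = multik.tables[3]
query = "ACG"
qv = table.lookup(query)
sims = {
    tok: float(qv @ v / (np.linalg.norm(qv) * np.linalg.norm(v)))
    for tok, v in table.vectors.items()
    if tok != query
}
top = sorted(sims, key=sims.get, reverse=True)[:3]
print(f"closest 3-mers to {query}: {[(t, round(sims[t], 3)) for t in top]}")
print("(vectors are context-shaped: neighbours co-occur with the query in the corpus)")
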
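"""Pathology gene-list overlap and over-representation testing.

Tests whether a signature gene set shares more genes with a pathology list
than random sets of the same size drawn from the background (permutation
null with add-one smoothing), cross-checks against the exact
hypergeometric tail, and runs a small GMT-style ORA with BH-FDR.
"""

from plscortex import (
    hypergeometric_tail,
    make_pathology_sets,
    ora,
    permutation_overlap_test,
)

background = [f"GENE{i:05d}" for i in range(2000)]
signature = background[:150]
pathology = make_pathology_sets(background, signature, overlap_fraction=0.5,
                                set_size=400, seed=5)

res = permutation_overlap_test(set(signature), pathology, background,
                               n_perm=1000, seed=9)
print(f"observed overlap: {res.observed} of {res.query_size} signature genes")
print(f"null mean: {res.null_counts.mean():.1f} "
      f"(chance = query x target / background = "
      f"{res.query_size * res.target_size / res.background_size:.1f})")
print(f"permutation p = {res.p_value:.4f}")
exact = hypergeometric_tail(res.observed, res.query_size, res.target_size,
                            res.background_size)
print(f"exact hypergeometric tail = {exact:.2e} (permutation floor is 1/1001)")

terms = {
    "pathology_list": pathology,
    "random_term": set(background[1000:1400]),
}
enr = ora(set(signature), terms, background, q_threshold=0.05)
print("\nORA against a 2-term collection (overlap, p, q, significant):")
print(enr.table[["overlap", "p", "q", "significant"]].round(4))
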
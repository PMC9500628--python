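"""GO over-representation of a DEI gene set.

Hypergeometric upper-tail test per term with BH q-values per namespace,
then the union of genes from significant terms — the candidate set that
genomic integration will scan.
"""

from isogx import enrichment
from isogx.simulate import CohortDesign, generate_cohort

cohort = generate_cohort(CohortDesign(seed=1))
dei_genes = set(cohort.truth.planted_dei["gene_id"])
universe = set(cohort.annotations.gene_model.genes.index)

res = enrichment.enrich(dei_genes, cohort.annotations.go, universe, run="I_consistent")
print(res[["namespace", "term_id", "k", "K", "p", "q"]].to_string(index=False))
union = enrichment.candidate_union([res])
print(f"\ncandidate genes from significant terms: {len(union)}")
# k of K term genes hit by the n-gene DEI set out of an N-gene universe;
# terms pass at p < 0.01 and q < 0.05.
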
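"""Map differential metabolites to genes and test pathway overrepresentation.

The differential metabolite list from the previous step is converted to its
mapped gene union, which is then scored against the gene-set collection by
the upper-tail hypergeometric test with BH q-values.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, STUDY

from metsig import (
    differential_features,
    generate_mapping_and_genesets,
    generate_metabolomics,
    hypergeometric_enrichment,
    map_metabolites_to_genes,
    normalize_metabolites,
    significant_features,
)


def main():
    matrix, annot, _ = generate_metabolomics(STUDY)
    diff = significant_features(
        differential_features(normalize_metabolites(matrix), annot, "metabolite")
    )
    mapping, collection = generate_mapping_and_genesets(STUDY)
    genes, provenance = map_metabolites_to_genes(diff, mapping)
    enrichment = hypergeometric_enrichment(genes, collection)

    RESULTS.mkdir(exist_ok=True)
    enrichment.to_csv(RESULTS / "03_enrichment.tsv", sep="\t", float_format="%.6g")
    provenance.to_csv(RESULTS / "03_mapped_genes.tsv", sep="\t", index=False)
    n_sig = int(enrichment["significant"].sum())
    print(f"{len(diff)} differential metabolites mapped to {len(genes)} genes")
    print(f"{n_sig} of {len(enrichment)} gene sets overrepresented at p < 0.05")
    print("top sets:")
    print(enrichment.head(3)[["N", "K", "n", "k", "p", "q"]].to_string())


if __name__ == "__main__":
    main()
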
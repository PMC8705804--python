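"""From summary statistics to a disease-disease network and an ego network.

Runs the association scan on the reference cohort, applies the standard
filters (p <= 1e-4, MAF >= 0.01, cases >= 200, LD pruning), builds the
binary disease-SNP matrix, and extracts the egocentric network of the first
ego disease.
"""

from egoddn import (
    FilterConfig,
    association_scan,
    build_full_ddn,
    build_matrix,
    category_composition,
    extract_ego_network,
    filter_associations,
    ld_prune,
    simulate_cohort,
)
from egoddn.reference import reference_config, reference_egos

cohort = simulate_cohort(reference_config(seed=1))
records = association_scan(cohort)
phenos = cohort.phenotype_info()
print(f"association scan: {len(records)} (disease, SNP) tests")

cfg = FilterConfig()
kept = ld_prune(filter_associations(records, phenos, cfg), cohort.genotypes, cfg)
matrix = build_matrix(kept)
print(f"after filtering: {len(kept)} significant associations, "
      f"{len(matrix.phecodes)} diseases x {len(matrix.snp_ids)} SNPs")

ddn = build_full_ddn(matrix, phenos)
print(f"full DDN: {len(ddn.nodes)} nodes, {len(ddn.edges)} edges "
      "(an edge means >= 1 shared significant SNP)")

ego = reference_egos()[0]
net = extract_ego_network(ddn, ego)
print(f"egocentric network of {ego}: alters = {net.alters}")
for alter in net.alters:
    ann = ddn.edge(ego, alter)
    print(f"  {ego}-{alter}: {ann.count_weight} shared SNPs, "
          f"cosine weight {ann.cosine_weight:.3f}")
print("alter composition by category:", category_composition(net, phenos))
print("Edge weights feed the propagation step; heavier edges mean more "
      "shared genetic signal with the ego disease.")
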
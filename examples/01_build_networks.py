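"""Build the disease-gene and disease-gene-pathway networks from mapping tables.

Generates a small synthetic study (four TSV tables with planted structure),
normalizes gene symbols against the authority table, then builds the
bipartite disease-gene network, its disease-pair projection, and the
tripartite code-gene-pathway network, exporting standard graph files.
"""

from pathlib import Path

from diseasome import (
    SyntheticConfig,
    build_bipartite,
    build_tripartite,
    disease_pathway_profiles,
    disease_profiles,
    export_network,
    generate_study,
    normalize_symbols,
    project_disease_pairs,
    read_table,
)

out = Path("scratch/example01")
study = generate_study(SyntheticConfig(seed=42))
study.write(out)

# Read the tables back the way a user with real files would.
dg = read_table(out / "disease_gene.tsv", "disease_gene")
hgnc = read_table(out / "hgnc.tsv", "hgnc")
gp = read_table(out / "gene_pathway.tsv", "gene_pathway")
print(f"disease-gene rows: {dg.n_rows} ({dg.n_duplicates} duplicates merged)")

# Symbols in the disease-gene table may be previous/alias forms; rewrite
# them to approved symbols before any network construction.
normed, report = normalize_symbols(dg.records, hgnc.records)
print(
    f"normalization: {report.n_already_approved} already approved, "
    f"{report.n_mapped_via_previous_or_alias} rewritten, "
    f"{report.n_dropped_unmatched} dropped"
)

net = build_bipartite(normed)
profiles = disease_profiles(net)
pairs = project_disease_pairs(profiles)
print(
    f"bipartite network: {len(net.disease_nodes)} codes x "
    f"{len(net.gene_nodes)} genes, {net.n_edges} associations"
)
print(f"gene-sharing disease pairs: {len(pairs)}")

triples = build_tripartite(normed, gp.records)
ppros = disease_pathway_profiles(triples)
ppairs = project_disease_pairs(ppros)
print(f"tripartite network: {len(triples)} code-gene-pathway interactions")
print(f"pathway-sharing disease pairs: {len(ppairs)}")

export_network(net, out / "bipartite.graphml", "graphml")
export_network(pairs, out / "disease_pairs.tsv", "edge_list_tsv")
print(f"wrote {out}/bipartite.graphml and {out}/disease_pairs.tsv")
print(
    "Each disease-pair edge weight is the number of shared genes; the "
    "GraphML opens in any standard graph tool."
)
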
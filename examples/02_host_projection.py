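"""Which bacteria share phages? One-mode projection statistics.

Projects the infection matrix onto its permissive hosts: two bacteria are
linked when at least one phage infects both, weighted by how many do. The
pair and neighbor statistics quantify opportunities for phage-mediated gene
transfer between species, biomes and resistance phenotypes.
"""

from phagenet import (
    MatrixSpec,
    drop_uninfected_hosts,
    gen_incidence,
    neighbor_stats,
    pair_shared_stats,
    project,
    rank_sum_test,
    species_network,
)

spec = MatrixSpec(n_hosts=123, n_phages=94, structure="nested",
                  fill=0.15, noise=0.05, seed=3)
matrix, hosts, _ = gen_incidence(spec)
reduced, _ = drop_uninfected_hosts(matrix)
graph = project(reduced, hosts=[h for h in hosts if h.host_id in reduced.host_ids])
print(f"{graph.graph['H']} hosts, {graph.graph['n_interactions']} connected pairs "
      f"of {graph.graph['n_pairs']} (connectance {graph.graph['connectance']:.2f})")

overall = pair_shared_stats(graph, "overall")["overall"]
print(f"shared phages per host pair: {overall['mean']:.1f} +- {overall['sd']:.1f} "
      f"(max {overall['max']} between {overall['max_pair']})")

by_species = pair_shared_stats(graph, "species")
same, diff = by_species["same_species"], by_species["different_species"]
print(f"within species:  {same['mean']:.1f} +- {same['sd']:.1f} (n = {same['n']})")
print(f"between species: {diff['mean']:.1f} +- {diff['sd']:.1f} (n = {diff['n']})")

# are same-species pairs better connected than cross-species pairs?
from itertools import combinations

w_same, w_diff = [], []
for u, v in combinations(graph.nodes, 2):
    w = graph.get_edge_data(u, v, {"weight": 0})["weight"]
    if graph.nodes[u]["record"].species == graph.nodes[v]["record"].species:
        w_same.append(w)
    else:
        w_diff.append(w)
test = rank_sum_test(w_same, w_diff)
print(f"rank-sum test within vs between species: W = {test.W:.0f}, p = {test.p:.3g}")

neighbors = neighbor_stats(graph)
print(f"neighbors per strain: {neighbors['mean']:.1f} +- {neighbors['sd']:.1f} "
      f"(max {neighbors['max']}, strain {neighbors['argmax']})")

resistant_to_susceptible = neighbor_stats(
    graph,
    neighbor_filter=lambda focal, n: n.resistance == "susceptible",
    focal_filter=lambda focal: focal.resistance in ("resistant", "MDR"),
)
print(f"drug-susceptible neighbors per drug-resistant host: "
      f"{resistant_to_susceptible['mean']:.1f} +- {resistant_to_susceptible['sd']:.1f}")

sp_net = species_network(graph, reduced, hosts)
flagged = [(u, v, d["weight"]) for u, v, d in sp_net.edges(data=True) if d["flagged"]]
print(f"species network: {sp_net.number_of_nodes()} species, "
      f"{sp_net.number_of_edges()} edges, {len(flagged)} sharing >20 phages")

# High between-stratum means show that phages link hosts across species,
# biome and resistance boundaries - the premise for cross-boundary
# horizontal gene transfer.
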
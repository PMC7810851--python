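"""Extract a vein graph from a rendered scene and compute its indexes.

Shows the whole graph route: skeleton -> traced multigraph ->
simplified graph -> cost / efficiency / centrality / resiliency report.
"""

import warnings

import veinnet as vn

warnings.filterwarnings("ignore")

scene = vn.generate_vein_scene(seed=7)
mask = vn.segment_frame(scene.frame)
skel = vn.skeletonize_with_width(mask)
graph = vn.simplify_graph(vn.extract_graph(skel))

report = vn.network_report(graph, reps=30, rng_seed=0)

# extracted counts exceed the planted vein graph: the pseudopod fans
# and the initial-cell disc contribute medial-axis branches of their own
print(f"nodes {report.n_nodes}, edges {report.n_edges} "
      f"(planted vein graph: {scene.truth_graph.number_of_nodes()} nodes, "
      f"{scene.truth_graph.number_of_edges()} edges)")
print(f"mean degree          {report.mean_degree:6.2f}")
print(f"alpha (cycle density){report.alpha:6.2f}")
print(f"wiring cost          {report.wiring_cost_length:6.1f} mm")
print(f"tortuosity           {report.tortuosity:6.3f}   (1 = straight veins)")
print(f"normalized length    {report.nnl:6.3f}   (0 = MST, 1 = Delaunay)")
print(f"length efficiency    {report.le:6.3f}   (1 = straight-line optimum)")
print(f"drag efficiency mean {report.drageff_mean:6.3f}   (vs 0.5 mm reference vein)")
print(f"mean betweenness     BL {report.mu_bl:5.2f}%  BD {report.mu_bd:5.2f}%")
for p in (25, 50, 75):
    print(f"fault tolerance p={p}: raw {report.ft_raw[p]:.3f} "
          f"normalized {report.ft_norm[p]:.3f}")
# A loopy vein network sits between its two reference graphs: NNL a bit
# above 0 (cheaper than the Delaunay bound), fault tolerance between
# the fragile spanning tree (0) and the maximally connected bound (1).
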
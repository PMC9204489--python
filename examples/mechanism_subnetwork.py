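"""Extract the target → disease-protein subnetwork behind one compound.

Takes the most proximal compound of a synthetic screen and pulls out its
mechanism subnetwork: its protein targets, the disease proteins they touch
directly, and (optionally) one-hop bridge proteins connecting the two sides.
The node and edge tables this prints are what a graph-visualization tool
would ingest.
"""

from netprox import extract_subnetwork, generate_scenario

scenario = generate_scenario(seed=31, n_nodes=300, module_size=20,
                             n_proximal=5, n_distal=5,
                             targets_per_compound=(5, 10))
cti = scenario.cti_table()
compound = "proximal_00"

direct = extract_subnetwork(
    compound, cti, scenario.disease_module, scenario.interactome
)
bridged = extract_subnetwork(
    compound, cti, scenario.disease_module, scenario.interactome,
    include_bridges=True,
)

print(f"compound {compound}:")
print(f"  targets: {len(direct.target_nodes)}")
print(f"  disease proteins adjacent to a target: {len(direct.disease_nodes)}")
print(f"  with one-hop bridges: +{len(bridged.bridge_nodes)} bridge protein(s), "
      f"{len(bridged.disease_nodes)} disease protein(s) reached")
print()
print(direct.edge_table().head(10).to_string(index=False))
print("(ppi rows are interactome edges inside the subnetwork; "
      "cti rows are compound-to-target links)")
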
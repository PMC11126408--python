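"""Patch connectivity indices, the distance-threshold sweep, and hub selection.

Core and bridge components form a graph whose links join patches within a
distance threshold.  IIC and PC summarise network connectivity; each patch's
importance is the percent drop (dIIC / dPC) when it is removed.  The sweep
shows how importance stabilises as the threshold grows — the rationale for
the 2000 m working threshold — and the top-ranked patches become hubs.
"""
from ginet import (
    PatchGraph,
    SceneParams,
    classify,
    delta_importance,
    extract_patches,
    generate_scene,
    gi_mask,
    iic,
    importance_table,
    pairwise_distances,
    pc,
    rank_and_select_hubs,
    threshold_sweep,
)

scene = generate_scene(SceneParams(seed=7))
cls = classify(gi_mask(scene.landuse))
patches = extract_patches(cls)
cell = scene.landuse.cell_size
A_L = scene.landuse.values.size * scene.landuse.cell_area_ha
d = pairwise_distances(patches, cell)

graph = PatchGraph(patches=patches, A_L=A_L, d=d, theta=2000.0)
print(f"{len(patches)} patches;  IIC = {iic(graph):.6f}  PC = {pc(graph):.6f}")

sweep = threshold_sweep(
    patches, A_L, [500, 1000, 1500, 2000, 3000, 4000],
    probe_patches=[p.id for p in patches[:4]], cell_size=cell, d=d,
)
print("\ndIIC of the four largest patches across thresholds (m):")
print(sweep.pivot(index="threshold_m", columns="patch_id", values="dIIC").round(2).to_string())

hubs = rank_and_select_hubs(delta_importance(graph), k=min(6, len(patches)))
print("\nimportance ranking (top rows become hubs, 'extremely important'):")
print(importance_table(hubs).round(3).to_string(index=False))
print("\nFlat rows beyond ~2000 m mean added links no longer change patch")
print("importance, so 2000 m is a stable working threshold.")
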
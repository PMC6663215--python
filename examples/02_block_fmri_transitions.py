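"""Detect stimulus-block transitions in simulated multivoxel fMRI.

Simulates a two-session, 8-category block-design experiment (24-s blocks,
TR 2.5 s, 242 frames, 577 voxels, double-gamma hemodynamic response), builds
a shape graph with a 2-D PCA lens at resolution 17 / gain 3, projects it
back to the time domain as a temporal connectivity matrix (TCM), and shows
that connectivity is high inside stimulus blocks and dips at block
boundaries, while same-category frames are far more connected than
frames from different categories.
"""

import shapegraph as sg

cfg = sg.haxby_like_preset()
data, labels = sg.generate_block_fmri(cfg)
print(f"simulated {data.n_samples} frames x {data.n_features} voxels, "
      f"categories: {', '.join(c for c in labels.categories if c != 'rest')}")

# unit-norm frames: correlation-style geometry for multivoxel patterns
data = sg.normalize_frames(data)
graph = sg.run_mapper(
    data,
    sg.MapperConfig(lens=sg.LensConfig("pca", n_components=2, seed=0),
                    resolution=17, gain=3),
)
print(f"shape graph: {graph.n_nodes} nodes, {graph.n_edges} edges")

tcm = sg.build_tcm(graph)
degree = sg.degree_series(tcm)

# align stimulus labels with the ~5 s hemodynamic lag (2 frames at TR 2.5 s)
aligned = labels.shifted(2)
interior, boundary = sg.block_frame_sets(aligned)
print(f"mean normalized TCM degree inside blocks:   {degree[interior].mean():.4f}")
print(f"mean normalized TCM degree at boundaries:   {degree[boundary].mean():.4f}")

sim = sg.category_similarity(tcm, aligned)
print(f"category similarity, same-category mean:    {sim.diagonal_mean():.3f}")
print(f"category similarity, cross-category mean:   {sim.offdiagonal_mean():.3f}")
# Interpretation: frames inside a block share nodes with the other frames of
# that category (high degree, high same-category similarity); frames at block
# boundaries carry intermediate hemodynamic ramps that resemble few other
# frames, so their connectivity dips — the graph localizes state transitions
# at single-frame resolution.
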
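"""Mini end-to-end experiment: correlation distances and resolvable scale.

Propagates pattern ensembles at five spatial scales through the EEG and
fMRI forward models, thresholds the sensor-pair correlation magnitude at
0.5, and reads the resolvable spatial pattern scale off the smoothing
spline of correlation distance vs log10 scale area.  Small mesh and
ensemble keep this to ~1 minute; the full experiment is `neuroscale run`.
"""

import numpy as np

from neuroscale import ExperimentConfig, run_experiment

cfg = ExperimentConfig(
    mesh_level=4,
    n_instances=100,
    scales=(6, 42, 162, 642, 2562),
    modalities=("eeg", "fmri"),
    fmri={
        "voxel_size": 0.3,
        "min_nodes": 1,
        "min_gm_fraction": 0.2,
        "cortical_thickness": 0.3,
        "z_range": (1.0, 2.5),
    },
    master_seed=3,
)
res = run_experiment(cfg)

print(f"{'modality':8s} {'scale cm^2':>10s} {'CTF':>7s} {'corr dist cm':>13s}")
for mod, per_scale in res.stats.items():
    for area in sorted(per_scale):
        st = per_scale[area]
        print(f"{mod:8s} {area:10.2f} {st.ctf_mean:7.2f} {st.corr_distance_mean:9.2f} ± {st.corr_distance_sd:.2f}")
for mod, curve in res.curves.items():
    tag = f"{curve.resolvable_scale:.2f} cm^2" if curve.defined else "undefined"
    print(f"resolvable spatial pattern scale [{mod}]: {tag}")
print("-> fMRI voxels decorrelate within ~a voxel of the activation extent;")
print("   EEG stays correlated across most of the cap at every scale")
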
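"""Smooth-cortex control: what do the folds do to the strain field?

Drives the sulcated mesh and the smooth (unfolded) control mesh with the
same profile-1 impact and compares cortical strain: folding should
concentrate strain in the sulcal fundi while lowering it in the remaining
(gyral) cortex relative to the smooth control.

Writes results/control/contrast.csv and VTK files for inspection.
"""

from pathlib import Path

import pandas as pd

from sulcalstrain import geometry as G
from sulcalstrain import kinematics as K
from sulcalstrain import solver as S
from sulcalstrain import vtkio
from sulcalstrain.pipeline import RunConfig

OUT = Path("results/control")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig.smoke()
    mats = cfg.materials()
    ev = K.generate_impact_pulse(cfg.profile_specs()[0], rng_seed=7)

    sulc_mesh, sulc_atlas = cfg.build_mesh()
    cfg_smooth = RunConfig.smoke()
    cfg_smooth.mesh_kind = "smooth"
    smooth_mesh, smooth_atlas = cfg_smooth.build_mesh()

    sf = S.simulate_impact(sulc_mesh, mats, ev.trace,
                           duration=cfg.sim_duration)
    sfm = S.simulate_impact(smooth_mesh, mats, ev.trace,
                            duration=cfg.sim_duration)

    sulcal = sf.peak_strain[sulc_atlas.element_mask("sulcal")].mean()
    gyral = sf.peak_strain[sulc_atlas.element_mask("gyral")].mean()
    smooth = sfm.peak_strain[
        smooth_atlas.region_label == G.LABEL_SMOOTH_CORTEX].mean()

    table = pd.DataFrame([
        {"region": "sulcated mesh, sulcal fundi", "mean_peak_strain": sulcal},
        {"region": "sulcated mesh, gyral crowns", "mean_peak_strain": gyral},
        {"region": "smooth control, cortex", "mean_peak_strain": smooth},
    ])
    table.to_csv(OUT / "contrast.csv", index=False)
    vtkio.write_vtk(OUT / "sulcated_strain.vtk", sulc_mesh,
                    {"peak_strain": sf.peak_strain,
                     "region": sulc_atlas.region_label})
    vtkio.write_vtk(OUT / "smooth_strain.vtk", smooth_mesh,
                    {"peak_strain": sfm.peak_strain,
                     "region": smooth_atlas.region_label})

    print(table.round(4).to_string(index=False))
    print(f"\nsulcal/gyral ratio: {sulcal / gyral:.2f} "
          f"(folding concentrates strain at the fundi)")
    print(f"smooth cortex vs sulcated gyral cortex: {smooth:.3f} vs "
          f"{gyral:.3f} (folding shields the non-sulcal cortex)")
    print(f"wrote {OUT}/contrast.csv and VTK fields for ParaView")


if __name__ == "__main__":
    main()
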
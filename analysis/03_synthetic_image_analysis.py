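"""Image-analysis chain on synthetic cells with known ground truth.

Generates a cohort of synthetic 3D cells (tubular filaments + vesicles inside
an ellipsoidal boundary), runs segmentation-style labeling, skeletonization
with spur pruning and junction untangling, punctate classification, and
contact detection, then compares the measurements against the generator's
ground truth.  Writes per-cell summaries to results/synthetic_cells.csv and
the per-contact table to results/synthetic_contacts.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from polkadots.contacts import (
    find_contacts,
    locate_contact,
    measure_cell,
    summarize_cell,
)
from polkadots.preprocess import label_components
from polkadots.synth import SynthConfig, synthesize_cell

OUT = Path(__file__).resolve().parents[1] / "results"
N_CELLS = 20


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cell_rows, contact_rows = [], []
    len_errors = []
    for seed in range(N_CELLS):
        # gently curved filaments (8 deg/step) pack less densely than the
        # default composition allows, so use a slightly sparser cell
        cfg = SynthConfig(seed=seed, curvature_bound=8.0,
                          n_filaments=10,
                          filament_length_dist=("uniform", 40, 120),
                          n_vesicles=20,
                          placement_mode=("end_biased", 0.5),
                          max_retries=2000)
        cell = synthesize_cell(cfg)
        bl, nb = label_components(cell.filaments)
        vl, _ = label_components(cell.vesicles)
        meas = measure_cell(bl, nb)
        contacts = find_contacts(bl, vl)
        for c in contacts:
            locate_contact(c, meas[c.bcl10_structure_id])
            contact_rows.append({
                "cell": seed,
                "structure": c.bcl10_structure_id,
                "vesicle": c.autophagosome_id,
                "class": c.contact_class,
                "end_distance_nm": c.end_distance * 25.0
                if np.isfinite(c.end_distance) else np.nan,
                "rescaled": c.rescaled_distance,
            })
        s = summarize_cell(meas, contacts)
        cell_rows.append({
            "cell": seed,
            "n_structures": s.n_structures,
            "n_puncta": s.n_puncta,
            "puncta_fraction": s.puncta_fraction,
            "fraction_over_1um": s.fraction_over_1um,
            "n_contacts": s.n_contacts,
            "mean_length_nm": s.mean_filament_length_nm,
        })
        measured = sorted(m.length_nm / 25.0 for m in meas.values())
        truth = sorted(cell.truth.lengths)
        len_errors += [abs(m - t) / t for m, t in zip(measured, truth) if t > 0]

    pd.DataFrame(cell_rows).to_csv(OUT / "synthetic_cells.csv", index=False)
    pd.DataFrame(contact_rows).to_csv(OUT / "synthetic_contacts.csv", index=False)
    df = pd.DataFrame(contact_rows)
    print(f"{N_CELLS} cells, {len(df)} contacts "
          f"({(df['class'] == 'P').sum()} on puncta).")
    print(f"Skeleton length vs ground truth: mean |error| = "
          f"{np.mean(len_errors):.1%} over {len(len_errors)} filaments.")
    print(f"Median contact end distance: "
          f"{np.nanmedian(df['end_distance_nm']):.0f} nm "
          f"(end-biased placement pulls contacts toward filament tips).")
    print(f"Wrote {OUT / 'synthetic_cells.csv'} and "
          f"{OUT / 'synthetic_contacts.csv'}")


if __name__ == "__main__":
    main()
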
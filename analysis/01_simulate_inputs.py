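#!/usr/bin/env python
"""Generate the synthetic datasets used by the downstream analyses.

Writes, under results/synthetic/: cooperative and non-cooperative ITC
isotherms (CSV + protocol), before/after amide peak lists with five
perturbed residues, Debye bead-model scattering curves for open vs looped
chains, and one well of two-channel cell images — each with a truth.json
sidecar carrying the generating parameters.
"""

import json
from pathlib import Path

import numpy as np

from coopbind import io, synth
from coopbind.itc import BindingModelTwoSets

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 20260930


def jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(type(x))


def write_truth(d: Path, truth: dict) -> None:
    (d / "truth.json").write_text(json.dumps(truth, indent=2, default=jsonable) + "\n")


def main() -> None:
    protocol = synth.default_protocol()

    # -- ITC: cooperative (100x tighter second site) vs flat two-site binding
    scenarios = {
        "itc_cooperative": BindingModelTwoSets(
            n1=0.25, n2=0.25, K1=1e6, K2=1e8, dH1=-8.0, dH2=-12.0
        ),
        "itc_noncooperative": BindingModelTwoSets(
            n1=0.25, n2=0.25, K1=3e6, K2=3e6, dH1=-9.0, dH2=-11.0
        ),
    }
    noise_sd = 1.5e-11  # kcal, ~1% of the largest injection heat
    for name, model in scenarios.items():
        d = OUT / name
        d.mkdir(parents=True, exist_ok=True)
        iso = synth.gen_itc(model, protocol, noise_sd=noise_sd, seed=SEED)
        io.write_itc_csv(iso, d / "isotherm.csv")
        io.write_protocol(protocol, d / "protocol.yaml")
        write_truth(d, iso.ground_truth)
        print(f"{name}: {iso.n_injections} injections, "
              f"max |q| = {np.max(np.abs(iso.q)):.3g} kcal")

    # -- NMR: 5 perturbed residues on a 90-residue background
    d = OUT / "nmr"
    d.mkdir(parents=True, exist_ok=True)
    scenario = synth.PeakListScenario(
        n_residues=90, perturbed=frozenset([7, 21, 42, 63, 88]),
        shift_offset_h=0.1, jitter_sd=0.005,
        broadened=frozenset([12, 30, 55]), broaden_factor=0.1,
        seed=SEED,
    )
    before, after = synth.gen_peaklists(scenario)
    io.write_peaklist(before, d / "before.list")
    io.write_peaklist(after, d / "after.list")
    write_truth(d, before.ground_truth)
    print(f"nmr: 90 residues, perturbed {sorted(scenario.perturbed)}, "
          f"broadened {sorted(scenario.broadened)}")

    # -- SAXS: extended vs loop-compacted bead chains
    for geometry in ("open_chain", "looped_chain"):
        for n in (8, 16, 24):
            d = OUT / "saxs" / f"{geometry}_{n:02d}"
            d.mkdir(parents=True, exist_ok=True)
            model = getattr(synth.BeadModel, geometry)(n)
            curve = synth.gen_saxs(model, snr=100, seed=SEED + n)
            io.write_saxs_dat(curve, d / "curve.dat")
            write_truth(d, curve.metadata["ground_truth"])
    print("saxs: open/looped chains, N in {8, 16, 24} beads")

    # -- imaging: one well at rho = 0.8 plus an aggregate well
    d = OUT / "images_mixing"
    d.mkdir(parents=True, exist_ok=True)
    images, truth = synth.gen_images(
        synth.ImageScenario(n_cells=4, rho=0.8, noise_sd=2.0, seed=SEED)
    )
    for i, image in enumerate(images):
        io.write_tiff(image, d / f"cell_{i:03d}.tif", order=["nucleus", "red", "green"])
    write_truth(d, truth)

    d = OUT / "images_aggregates"
    d.mkdir(parents=True, exist_ok=True)
    images, truth = synth.gen_images(
        synth.ImageScenario(
            n_cells=4, spots_per_cell=0, n_aggregates=3,
            aggregate_contrast=11.0, fish_enrichment=2.5,
            noise_sd=0.0, seed=SEED,
        )
    )
    for i, image in enumerate(images):
        io.write_tiff(
            image, d / f"cell_{i:03d}.tif",
            order=["nucleus", "red", "green", "fish"],
        )
    write_truth(d, truth)
    print(f"images: mixing well (rho=0.8) and aggregate well under {OUT}")


if __name__ == "__main__":
    main()
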
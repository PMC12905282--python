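#!/usr/bin/env python
"""Fit the simulated titrations and quantify binding cooperativity.

Reads the isotherms written by 01_simulate_inputs.py, fits the
two-sets-of-sites model, and tabulates K_D per set, the cooperativity index
K_D1/K_D2, total stoichiometry, free energies and Wiseman c values.  A
cooperative titration (second site 100x tighter) should report an index
near 100 and the flat control an index near 1; both should fit a total
molar ratio near 0.5 oligonucleotide per protein monomer.
"""

import json
from pathlib import Path

import pandas as pd

from coopbind import io
from coopbind.itc import fit_isotherm

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for name in ("itc_cooperative", "itc_noncooperative"):
        d = ROOT / "synthetic" / name
        protocol = io.read_protocol(d / "protocol.yaml")
        iso = io.read_itc_csv(d / "isotherm.csv", protocol)
        fit2 = fit_isotherm(iso, protocol, "two_sets")
        fit1 = fit_isotherm(iso, protocol, "one_set")
        truth = json.loads((d / "truth.json").read_text())["params"]
        true_ratio = max(1 / truth["K1"], 1 / truth["K2"]) / min(
            1 / truth["K1"], 1 / truth["K2"]
        )
        # F-test: does freeing a second set of sites improve the fit more
        # than noise would?  With equal sites the two-sets model is
        # degenerate and its K_D ratio is not meaningful.
        n, p2, extra = fit2.n_obs, 6, 3
        f_stat = ((fit1.rss - fit2.rss) / extra) / (fit2.rss / (n - p2))
        rows.append(
            {
                "scenario": name,
                "n_total": fit2.params["n1"] + fit2.params["n2"],
                "kd_weak_uM": max(fit2.kd) * 1e6,
                "kd_tight_nM": min(fit2.kd) * 1e9,
                "cooperativity_index": fit2.cooperativity_index,
                "true_index": true_ratio,
                "dG_kcal_mol": [round(g, 2) for g in fit2.dG],
                "c_values": [round(c, 1) for c in fit2.c_values],
                "F_two_vs_one": round(f_stat, 1),
            }
        )
    table = pd.DataFrame(rows)
    out = ROOT / "itc_cooperativity.csv"
    table.to_csv(out, index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(f"\nwrote {out}")
    t = table.set_index("scenario")
    print(
        f"\ncooperative scenario: index "
        f"{t.loc['itc_cooperative', 'cooperativity_index']:.1f} "
        f"(truth 100) with F = {t.loc['itc_cooperative', 'F_two_vs_one']} — "
        "two plateaus demand the two-sets model and a high K_D1/K_D2."
    )
    print(
        f"non-cooperative scenario: F = "
        f"{t.loc['itc_noncooperative', 'F_two_vs_one']} — the second set of "
        "sites is not supported, so its K_D ratio carries no evidence of "
        "cooperativity (equal-site fits are degenerate under noise)."
    )


if __name__ == "__main__":
    main()
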
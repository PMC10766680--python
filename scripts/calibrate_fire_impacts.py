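#!/usr/bin/env python
"""Check the fire-impact coefficients against their three regime anchors.

The impact parameterization (bark damping, crown-scorch exponent, flame
height law, litter threshold, resprout restart) is calibrated so that:

  1. FI = 0.1 — mature stems are essentially untouched (kill probability
     below 2% for a 10 m larch), so whole-area low-intensity fires leave
     no visible stem-count response;
  2. FI = 0.5 — survivable for tall larch (kill probability clearly below
     one-half for a 10 m larch) while removing most small trees;
  3. FI = 1.0 — stand-replacing: kill probability >= 0.999 for every
     shipped species at every height.

This script recomputes the kill-probability surface for the shipped
defaults and reports each anchor, failing loudly if one is violated.
Use it when re-tuning ImpactParams, FireParams, or the species table.
"""

import sys

import numpy as np

import firelarch as fl
from firelarch.fire_impacts import ImpactParams


def main() -> int:
    species = fl.default_species()
    impact = ImpactParams()
    fire = fl.FireParams()
    heights = np.array([10.0, 50.0, 130.0, 300.0, 600.0, 1000.0, 1290.0])
    ok = True

    print(f"flame height law: h = {fire.flame_h_max_m} m * FI^{fire.flame_exponent}")
    print(f"k_bark = {impact.k_bark_per_cm}/cm, gamma = {impact.crown_gamma}, "
          f"fi_full = {impact.fi_full_litter}\n")

    larch = species["Dahurian larch"]
    p01 = fl.kill_probability(0.1, 1000.0, 350.0, larch, impact, fire)
    print(f"anchor 1  FI=0.1, 10 m larch: p_kill = {p01:.4f} (< 0.02 required)")
    ok &= p01 < 0.02

    p05 = fl.kill_probability(0.5, 1000.0, 350.0, larch, impact, fire)
    print(f"anchor 2  FI=0.5, 10 m larch: p_kill = {p05:.4f} (< 0.5 required)")
    ok &= p05 < 0.5

    worst = 1.0
    for tr in species.values():
        h = np.minimum(heights, tr.max_height_cm - 1.0)
        p = fl.kill_probability(1.0, h, 0.35 * h, tr, impact, fire)
        worst = min(worst, float(np.min(p)))
    print(f"anchor 3  FI=1.0, all species/heights: min p_kill = {worst:.6f} "
          f"(>= 0.999 required)")
    ok &= worst >= 0.999

    print("\nkill-probability table (Dahurian larch):")
    print("height_cm " + " ".join(f"FI={fi:3.1f}" for fi in (0.1, 0.3, 0.5, 0.8, 1.0)))
    for h in heights:
        row = [fl.kill_probability(fi, h, 0.35 * h, larch, impact, fire)
               for fi in (0.1, 0.3, 0.5, 0.8, 1.0)]
        print(f"{h:9.0f} " + " ".join(f"{p:6.3f}" for p in row))

    print("\nall anchors satisfied" if ok else "\nANCHOR VIOLATED")
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
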
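#!/usr/bin/env python
"""Degradation-correct a synthetic release study and fit the power law.

Generates a 4-day sampling-with-replacement release study (true kinetics
M_t/M_inf = 0.105 t^0.3, 11.41 ng releasable per cm², aliquots attenuated
by within-interval degradation at a 22.75 h half-life, 10% noise, 5
replicates), inflates each aliquot by the exact correction factor
k dt / (1 - e^{-k dt}), and fits the Korsmeyer-Peppas model per replicate.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import gfelute as g
from gfelute import io

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    spec = g.ReleaseSpec(seed=0)
    studies = g.gen_release_study(spec, label="pH4-like")
    io.write_results(io.studies_to_frame(studies), OUT / "release_study.csv",
                     metadata={"spec": spec})

    frames, fits = [], {}
    for study in studies:
        corr = g.correct_study(study, k=spec.k_true)
        m_inf = g.m_infinity(corr, study.wash_recovery)
        fits[study.replicate_id] = g.fit_power_law(corr, m_inf)
        frames.append(io.corrected_to_frame(corr, study.condition_label,
                                            study.replicate_id))
    io.write_results(pd.concat(frames, ignore_index=True),
                     OUT / "corrected_release.csv",
                     metadata={"half_life_h": 22.75})
    io.write_results(io.powerlaw_to_frame(fits), OUT / "powerlaw_fits.csv",
                     metadata={"half_life_h": 22.75})

    Ks = [f.K for f in fits.values()]
    ns = [f.n for f in fits.values()]
    print(f"K = {np.mean(Ks):.4f} ± {np.std(Ks, ddof=1):.4f} /h^n  (truth {spec.K})")
    print(f"n = {np.mean(ns):.3f} ± {np.std(ns, ddof=1):.3f}        (truth {spec.n})")
    print(f"slow-release regime: n well below 0.5 as expected for "
          f"non-Fickian, bond-modulated release")


if __name__ == "__main__":
    main()
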
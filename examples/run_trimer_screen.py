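"""Screen docked trimer models and assess per-residue RMSD convergence.

Generates a set of synthetic scored trimer models (some with buried
C-termini), shortlists them by interface energy, membrane plausibility and
polar interface contacts, then builds a toy trajectory and reports whether a
target residue's RMSD has converged.
"""

import numpy as np

from exomefunnel.simulate import make_synthetic_trimer
from exomefunnel.structure import (
    RmsdSeries,
    assess_convergence,
    rank_models,
)

# 50 synthetic "docked" models with external interface-energy scores
models = []
rng = np.random.default_rng(0)
for i in range(50):
    m, _ = make_synthetic_trimer(
        preset="buried" if i % 5 == 0 else "exposed",
        n_polar_pairs=int(rng.integers(0, 6)),
        seed=i,
        external_score=float(rng.normal(-20, 5)),
        name=f"dock{i:03d}",
    )
    models.append(m)

shortlist = rank_models(models, top_fraction=0.2)
print("top-20% shortlist after the membrane-plausibility filter:")
for e in shortlist[:5]:
    print(f"  {e.model.name}: energy {e.score:6.2f}, "
          f"{e.polar_contacts} polar interface contacts")
print(f"({len(shortlist)} plausible models kept; buried-C-terminus models "
      "were rejected)\n")

# toy RMSD series: a stable site vs. an unstable one
frames = np.arange(100.0)
stable = RmsdSeries(frames, 5.0 + 0.2 * np.sin(frames / 7.0))
unstable = RmsdSeries(frames, 5.0 + 2.0 * np.sin(frames / 7.0))
for label, series in (("stable site", stable), ("unstable site", unstable)):
    res = assess_convergence(series, window_fraction=0.5, spread_tol=1.0)
    print(f"{label}: converged={res.converged} "
          f"(window mean {res.mean:.2f} A, spread {res.spread:.2f} A)")
print("A converged residue settles into a narrow RMSD band over the final")
print("half of the trajectory; a spread beyond 1 A flags local instability.")
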
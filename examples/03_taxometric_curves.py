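"""Coherent-cut-kinetics curves on taxonic vs dimensional data.

Generates a two-group mixture and a matched one-factor dataset, computes the
averaged MAMBAC and MAXEIG curves on both, and prints curve summaries. The
taxonic curves peak in the interior; the dimensional curves stay flat or dip.
"""

import numpy as np

from lctax import (TaxonicSpec, lmode, make_dimensional, make_taxonic,
                   mambac_curves, match_dimensional_to_taxonic, maxeig_curves)

tax, _ = make_taxonic(TaxonicSpec(n_cases=600, base_rate=0.5, separation=2.0,
                                  n_categories=4, seed=31))
dim = make_dimensional(match_dimensional_to_taxonic(tax, seed=32))

for name, data in (("taxonic", tax), ("dimensional", dim)):
    mam = mambac_curves(data).averaged.y
    eig = maxeig_curves(data).averaged.y
    lm = lmode(data)
    print(f"{name}:")
    print(f"  MAMBAC  edge {mam[0]:.3f} / peak {mam.max():.3f} / edge {mam[-1]:.3f}")
    print(f"  MAXEIG  edge {eig[0]:.3f} / peak {eig.max():.3f} / edge {eig[-1]:.3f}")
    print(f"  L-Mode  modes at {lm.left_mode:.2f} and {lm.right_mode:.2f}, "
          f"clear bimodality: {lm.clear_bimodality}")
print()
print("Interior peaks well above the edges, and a clearly bimodal factor-score "
      "density, are the taxonic signatures; flat or bowl-shaped curves and a "
      "unimodal density are dimensional.")
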
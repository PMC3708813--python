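"""Steady-state residence times and the Putative Client Index.

Compares an independently evolving gene (PCI = 1 identically) with a
client-like gene that is almost never present without the focal chaperone
(PCI near 0). States: A=(focal-, gene-), B=(focal+, gene-),
C=(focal-, gene+), D=(focal+, gene+); PCI = C / ((C+D)(A+C)).
"""

import numpy as np

import coevoscan as cs

examples = {
    "independent (gain 1, loss 0.5 each)":
        cs.MODELS["independent"].expand(np.array([1.0, 0.5, 1.0, 0.5])),
    "client-like (q13=0.01 << q31=1)":
        cs.simulate.CLIENT_RATES.as_array(),
    "with zero rates (regularized)":
        np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]),
}

for label, rates in examples.items():
    reg = cs.regularize_rates(rates)
    ss = cs.steady_state(cs.build_generator(reg))
    print(f"{label}")
    print(f"  steady state A={ss.A:.3f} B={ss.B:.3f} C={ss.C:.3f} "
          f"D={ss.D:.3f}")
    print(f"  PCI = {cs.pci(ss):.4f}")
print("\n(PCI compares time spent in 'gene present without the focal "
      "chaperone' to its expectation under independence; values near 0 "
      "mark putative clients, 1 means no dependence)")
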
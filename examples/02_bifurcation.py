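"""Trace the transcritical bifurcation in the efferocytosis/death ratio.

Below mu_e/mu_a = 1 the deep plaque cannot sustain live foam cells (the
extinction state is stable); above it a coexistence state F* = 1 - mu_a/mu_e
takes over.  Prints the bifurcation table the `ode` CLI subcommand emits.
"""

import numpy as np

from plaquesim import bifurcation_table

table = bifurcation_table(np.round(np.linspace(0.25, 3.0, 12), 3), mu_a=40.0)
print(table.to_string(index=False, float_format=lambda x: f"{x:8.3f}"))
# Each row is a steady state: eigenvalue < 0 means stable.  Note the swap of
# stability between the F*=0 and coexistence branches at ratio 1.
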
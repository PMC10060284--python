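"""Small construction helpers shared across test modules."""

import numpy as np

from plaquesim import PlaqueState


def make_state(f, l, c, R=1.0, t=0.0):
    """Build a PlaqueState on a cell-centred unit grid from field values
    (scalars broadcast)."""
    f = np.atleast_1d(np.asarray(f, dtype=float))
    n = len(f)
    y = (np.arange(n) + 0.5) / n
    return PlaqueState(
        y_grid=y, f=f,
        l=np.broadcast_to(np.atleast_1d(l), (n,)).astype(float),
        c=np.broadcast_to(np.atleast_1d(c), (n,)).astype(float),
        R=R, t=t,
    )
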
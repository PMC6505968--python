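"""Shared helpers for the test-suite."""

import numpy as np

from brainabc.rejection import BatchResult


def synthetic_batch(distances, batch_index=0):
    """Wrap a raw distance vector as a BatchResult with index draws."""
    distances = np.asarray(distances, dtype=float)
    n = distances.size
    return BatchResult(
        draws={"p": np.arange(n, dtype=float)},
        distances=distances,
        per_channel={"ch": distances.copy()},
        n_failed=int(np.sum(~np.isfinite(distances))),
        batch_index=batch_index,
    )
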
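"""Weighted similarity between graphlet signatures (SigSim).

Two nodes are compared orbit by orbit on a log scale; each orbit's
contribution is weighted by how independent that orbit is from the others
(``w_i = 1 - log(o_i)/log(73)``).  The per-orbit distance between
signatures u and v is

    D_i = w_i * |log(u_i + 1) - log(v_i + 1)| / log(max(u_i, v_i) + 2)

and the similarity is ``1 - sum_i D_i / sum_i w_i``, a value in [0, 1] that
equals 1 exactly when the two signatures are identical.  Distances are
taken out to four hops, so SigSim is a stringent measure of local wiring.
"""

from __future__ import annotations

import numpy as np

from .graphlet_catalog import N_ORBITS, orbit_dependency_counts, orbit_weights

__all__ = [
    "orbit_weights",
    "orbit_dependency_counts",
    "signature_similarity",
    "pairwise_signature_similarity",
]


def signature_similarity(a, b, weights: np.ndarray | None = None) -> float:
    """SigSim between two 73-component graphlet signatures."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (N_ORBITS,) or b.shape != (N_ORBITS,):
        raise ValueError(f"signatures must have {N_ORBITS} components")
    w = orbit_weights() if weights is None else np.asarray(weights, dtype=float)
    dist = w * np.abs(np.log(a + 1.0) - np.log(b + 1.0)) / np.log(np.maximum(a, b) + 2.0)
    return float(1.0 - dist.sum() / w.sum())


def pairwise_signature_similarity(
    signatures: np.ndarray, weights: np.ndarray | None = None, chunk: int = 64
) -> np.ndarray:
    """Symmetric SigSim matrix for a stack of signatures (rows).

    Vectorised with row-chunking to bound memory; equivalent to calling
    :func:`signature_similarity` on every pair.
    """
    S = np.asarray(signatures, dtype=float)
    if S.ndim != 2 or S.shape[1] != N_ORBITS:
        raise ValueError(f"expected an (n, {N_ORBITS}) signature matrix")
    w = orbit_weights() if weights is None else np.asarray(weights, dtype=float)
    n = S.shape[0]
    logs = np.log(S + 1.0)
    out = np.empty((n, n), dtype=float)
    wsum = w.sum()
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block_logs = logs[start:stop, None, :]  # (c, 1, 73)
        diff = np.abs(block_logs - logs[None, :, :])
        denom = np.log(np.maximum(S[start:stop, None, :], S[None, :, :]) + 2.0)
        out[start:stop] = 1.0 - (w * diff / denom).sum(axis=2) / wsum
    return out
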
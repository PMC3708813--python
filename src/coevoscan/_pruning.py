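"""Low-level pruning (post-order partial-likelihood) kernel.

The kernel is compiled with numba when available; a vectorised numpy
fallback keeps the package functional without it. Both take the tree as
flat arrays prepared by :class:`coevoscan.markov.TreeLikelihood`:

- ``order``: node indices in post-order, root last;
- ``parent``: parent index per node (-1 for the root);
- ``P``: per-node transition matrix along the edge above the node
  (the root's slot is unused);
- ``partials``: per-node 4-vector of conditional likelihoods, pre-seeded
  with one-hot rows at the leaves and ones at internal nodes (mutated);
- ``prior``: root state distribution.

Per-node rescaling keeps the computation in a safe floating range on
large trees; the rescalings are accumulated into the returned
log-likelihood.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def _prune_py(order, parent, P, partials, prior):
    logscale = 0.0
    for i in order:
        vec = partials[i]
        s = vec.sum()
        if not s > 0.0:
            return -np.inf
        vec /= s
        logscale += np.log(s)
        p = parent[i]
        if p >= 0:
            partials[p] *= P[i] @ vec
    root = order[-1]
    lik = float(prior @ partials[root])
    if not lik > 0.0:
        return -np.inf
    return float(np.log(lik) + logscale)


if HAVE_NUMBA:

    @njit(cache=True, fastmath=True)
    def _prune_nb(order, parent, P, partials, prior):  # pragma: no cover
        logscale = 0.0
        n = order.shape[0]
        tmp = np.empty(4)
        for ii in range(n):
            i = order[ii]
            s = partials[i, 0] + partials[i, 1] + partials[i, 2] + partials[i, 3]
            if not s > 0.0:
                return -np.inf
            inv = 1.0 / s
            for j in range(4):
                partials[i, j] *= inv
            logscale += np.log(s)
            p = parent[i]
            if p >= 0:
                for j in range(4):
                    acc = 0.0
                    for k in range(4):
                        acc += P[i, j, k] * partials[i, k]
                    tmp[j] = acc
                for j in range(4):
                    partials[p, j] *= tmp[j]
        root = order[n - 1]
        lik = 0.0
        for j in range(4):
            lik += prior[j] * partials[root, j]
        if not lik > 0.0:
            return -np.inf
        return np.log(lik) + logscale

    prune = _prune_nb

    @njit(cache=True)
    def prune_eig(order, parent, lengths, w, V, Vinv, partials, prior):  # pragma: no cover
        """Fused kernel: per-edge transition applied via the generator's
        eigendecomposition, P·v = V·diag(exp(w·t))·(V⁻¹·v), so the full
        transition matrices are never materialised."""
        logscale = 0.0
        n = order.shape[0]
        y = np.empty(4, dtype=np.complex128)
        for ii in range(n):
            i = order[ii]
            s = partials[i, 0] + partials[i, 1] + partials[i, 2] + partials[i, 3]
            if not s > 0.0:
                return -np.inf
            inv = 1.0 / s
            for j in range(4):
                partials[i, j] *= inv
            logscale += np.log(s)
            p = parent[i]
            if p >= 0:
                t = lengths[i]
                for m in range(4):
                    acc = 0.0 + 0.0j
                    for k in range(4):
                        acc += Vinv[m, k] * partials[i, k]
                    y[m] = acc * np.exp(w[m] * t)
                for j in range(4):
                    acc = 0.0 + 0.0j
                    for m in range(4):
                        acc += V[j, m] * y[m]
                    val = acc.real
                    if val < 0.0:  # eigen round-off
                        val = 0.0
                    partials[p, j] *= val
        root = order[n - 1]
        lik = 0.0
        for j in range(4):
            lik += prior[j] * partials[root, j]
        if not lik > 0.0:
            return -np.inf
        return np.log(lik) + logscale

else:  # pragma: no cover
    prune = _prune_py
    prune_eig = None
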
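"""Convergence diagnostics."""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError

__all__ = ["rhat"]


def rhat(chains) -> float:
    """Split-chain potential scale reduction factor for one scalar parameter.

    Each chain is halved (an odd trailing draw is dropped), then the classic
    between/within variance ratio is applied to the 2m half-chains:
    R-hat = sqrt(((n-1)/n * W + B/n) / W).  Values near 1 indicate the
    chains mix over the same distribution; > 1.1 is the conventional
    warning level.
    """
    chains = [np.asarray(c, dtype=float).ravel() for c in chains]
    if len(chains) < 2:
        raise ValidationError("rhat needs at least 2 chains")
    if min(len(c) for c in chains) < 4:
        raise ValidationError("rhat needs at least 4 draws per chain")
    n = min(len(c) for c in chains) // 2
    halves = []
    for c in chains:
        halves.append(c[:n])
        halves.append(c[len(c) - n:])
    H = np.stack(halves)                     # (2m, n)
    W = H.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0
    Bn = H.mean(axis=1).var(ddof=1)          # B / n
    var_plus = (n - 1) / n * W + Bn
    return float(np.sqrt(var_plus / W))
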
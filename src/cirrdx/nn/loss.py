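"""Binary cross-entropy on logits, numerically stable."""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean BCE loss and its gradient w.r.t. the logits.

    loss_i = max(z,0) - z*y + log(1 + exp(-|z|))  (log-sum-exp form)
    """
    z = logits.astype(np.float64).ravel()
    y = targets.astype(np.float64).ravel()
    loss = float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - y) / z.size).astype(np.float32).reshape(logits.shape)
    return loss, grad
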
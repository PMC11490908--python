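"""Binary cross-entropy on probabilities, with the logit-space gradient.

Models keep their final affine layer linear and apply the logistic link
here, so the gradient passed back is the numerically stable ``p - y``.
"""

from __future__ import annotations

import numpy as np

from .layers import sigmoid

EPS = 1e-7


def binary_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Return ``(loss, probabilities, dlogits)`` for labels ``y`` in {0,1}.

    ``dlogits`` is already averaged over the batch.
    """
    z = logits.reshape(-1)
    y = np.asarray(y, dtype=z.dtype).reshape(-1)
    p = sigmoid(z)
    pc = np.clip(p, EPS, 1.0 - EPS)
    loss = float(-(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)).mean())
    dlogits = ((p - y) / z.size).reshape(logits.shape)
    return loss, p, dlogits
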
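"""Adam optimizer over a list of layers."""

from __future__ import annotations

import numpy as np


class Adam:
    """First/second-moment adaptive gradient steps (decay 0.9 / 0.999)."""

    def __init__(self, layers, learning_rate=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-7):
        self.layers = list(layers)
        self.lr, self.beta1, self.beta2, self.eps = learning_rate, beta1, beta2, eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in lay.params.items()}
                   for lay in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in lay.params.items()}
                   for lay in self.layers]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for lay, m, v in zip(self.layers, self._m, self._v):
            grads = lay.grads
            params = lay.params
            for k in params:
                g = grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                params[k] -= (self.lr * (m[k] / corr1)
                              / (np.sqrt(v[k] / corr2) + self.eps))

    def zero_grads(self):
        for lay in self.layers:
            lay.zero_grads()
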
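"""Network building blocks on top of the autodiff core.

Weight initialisation is Glorot-uniform from a caller-supplied
``numpy.random.Generator`` so that every network in the package is
bit-reproducible from its seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Adam, Tensor, concat, conv2d, upsample_nearest

__all__ = [
    "Dense",
    "Conv",
    "UpConv",
    "RNNCell",
    "LSTMCell",
    "GRUCell",
    "BiRecurrent",
    "dropout",
    "Adam",
    "Tensor",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)))
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class Conv:
    """3x3 convolution, stride configurable, 'same'-style padding 1."""

    def __init__(self, rng, c_in: int, c_out: int, stride: int = 1):
        fan_in, fan_out = c_in * 9, c_out * 9
        self.W = Tensor(_glorot(rng, fan_in, fan_out, (c_out, c_in, 3, 3)))
        self.b = Tensor(np.zeros(c_out))
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.W, self.b, stride=self.stride, pad=1)

    @property
    def params(self):
        return [self.W, self.b]


class UpConv:
    """Nearest-neighbour x2 upsampling followed by a 3x3 convolution."""

    def __init__(self, rng, c_in: int, c_out: int):
        self.conv = Conv(rng, c_in, c_out, stride=1)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(upsample_nearest(x, 2))

    @property
    def params(self):
        return self.conv.params


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask, requires_grad=False)


class RNNCell:
    """Vanilla tanh recurrent unit."""

    def __init__(self, rng, n_in: int, n_hidden: int):
        self.W = Tensor(_glorot(rng, n_in + n_hidden, n_hidden, (n_in + n_hidden, n_hidden)))
        self.b = Tensor(np.zeros(n_hidden))
        self.n_hidden = n_hidden

    def init_state(self, batch: int):
        return (Tensor(np.zeros((batch, self.n_hidden)), requires_grad=False),)

    def step(self, x: Tensor, state):
        (h,) = state
        h = (concat([x, h]) @ self.W + self.b).tanh()
        return h, (h,)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def input_weights(self):
        return self.W  # rows [0, n_in) are the input-to-hidden weights


class LSTMCell:
    def __init__(self, rng, n_in: int, n_hidden: int):
        d = n_in + n_hidden
        self.Wi = Tensor(_glorot(rng, d, n_hidden, (d, n_hidden)))
        self.Wf = Tensor(_glorot(rng, d, n_hidden, (d, n_hidden)))
        self.Wo = Tensor(_glorot(rng, d, n_hidden, (d, n_hidden)))
        self.Wg = Tensor(_glorot(rng, d, n_hidden, (d, n_hidden)))
        self.bi = Tensor(np.zeros(n_hidden))
        self.bf = Tensor(np.ones(n_hidden))  # forget bias 1: remember by default
        self.bo = Tensor(np.zeros(n_hidden))
        self.bg = Tensor(np.zeros(n_hidden))
        self.n_in = n_in
        self.n_hidden = n_hidden

    def init_state(self, batch: int):
        z = np.zeros((batch, self.n_hidden))
        return (Tensor(z.copy(), requires_grad=False), Tensor(z.copy(), requires_grad=False))

    def step(self, x: Tensor, state):
        h, c = state
        xh = concat([x, h])
        i = (xh @ self.Wi + self.bi).sigmoid()
        f = (xh @ self.Wf + self.bf).sigmoid()
        o = (xh @ self.Wo + self.bo).sigmoid()
        g = (xh @ self.Wg + self.bg).tanh()
        c = f * c + i * g
        h = o * c.tanh()
        return h, (h, c)

    @property
    def params(self):
        return [self.Wi, self.Wf, self.Wo, self.Wg, self.bi, self.bf, self.bo, self.bg]

    def input_weight_l1(self) -> Tensor:
        """L1 norm of the input-feature weights of all four gates."""
        total = None
        for W in (self.Wi, self.Wf, self.Wo, self.Wg):
            term = W[: self.n_in, :].abs().sum()
            total = term if total is None else total + term
        return total


class GRUCell:
    def __init__(self, rng, n_in: int, n_hidden: int):
        d = n_in + n_hidden
        self.Wz = Tensor(_glorot(rng, d, n_hidden, (d, n_hidden)))
        self.Wr = Tensor(_glorot(rng, d, n_hidden, (d, n_hidden)))
        self.Wn = Tensor(_glorot(rng, n_in, n_hidden, (n_in, n_hidden)))
        self.Un = Tensor(_glorot(rng, n_hidden, n_hidden, (n_hidden, n_hidden)))
        self.bz = Tensor(np.zeros(n_hidden))
        self.br = Tensor(np.zeros(n_hidden))
        self.bn = Tensor(np.zeros(n_hidden))
        self.n_hidden = n_hidden

    def init_state(self, batch: int):
        return (Tensor(np.zeros((batch, self.n_hidden)), requires_grad=False),)

    def step(self, x: Tensor, state):
        (h,) = state
        xh = concat([x, h])
        z = (xh @ self.Wz + self.bz).sigmoid()
        r = (xh @ self.Wr + self.br).sigmoid()
        n = (x @ self.Wn + (r * h) @ self.Un + self.bn).tanh()
        h = (1.0 - z) * n + z * h
        return h, (h,)

    @property
    def params(self):
        return [self.Wz, self.Wr, self.Wn, self.Un, self.bz, self.br, self.bn]


_CELLS = {"simple": RNNCell, "lstm": LSTMCell, "gru": GRUCell}


class BiRecurrent:
    """Bidirectional recurrent layer returning the concatenated final states."""

    def __init__(self, rng, nn_type: str, n_in: int, n_hidden: int, bidirectional: bool = True):
        if nn_type not in _CELLS:
            raise ValueError(f"unknown nn_type {nn_type!r}; expected one of {sorted(_CELLS)}")
        self.fwd = _CELLS[nn_type](rng, n_in, n_hidden)
        self.bwd = _CELLS[nn_type](rng, n_in, n_hidden) if bidirectional else None
        self.nn_type = nn_type

    def __call__(self, xs: list[Tensor]) -> Tensor:
        batch = xs[0].shape[0]
        state = self.fwd.init_state(batch)
        for x in xs:
            h, state = self.fwd.step(x, state)
        outputs = [h]
        if self.bwd is not None:
            state = self.bwd.init_state(batch)
            for x in reversed(xs):
                hb, state = self.bwd.step(x, state)
            outputs.append(hb)
        return concat(outputs) if len(outputs) > 1 else outputs[0]

    @property
    def out_dim(self):
        n = self.fwd.n_hidden
        return 2 * n if self.bwd is not None else n

    @property
    def params(self):
        p = list(self.fwd.params)
        if self.bwd is not None:
            p += self.bwd.params
        return p

    def input_weight_l1(self):
        if self.nn_type != "lstm":
            return None
        total = self.fwd.input_weight_l1()
        if self.bwd is not None:
            total = total + self.bwd.input_weight_l1()
        return total
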
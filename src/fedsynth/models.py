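"""Tabular generative models: a conditional tabular GAN and a DDPM.

Both train on the encoded representation produced by :mod:`fedsynth.preprocess`
and sample back to table space through ``inverse_transform``.

The GAN follows the CTGAN recipe: a conditional vector drawn by
training-by-sampling over the categorical columns, a pac-grouped critic with
the Wasserstein loss plus gradient penalty, gumbel-softmax relaxation
(temperature 0.2) of the one-hot output blocks, and an extra generator
cross-entropy between the conditioning vector and the generated block of the
conditioned column.  The diffusion model is a standard continuous-space DDPM
over the encoded table (one-hot blocks treated as continuous and re-argmaxed
at decode): linear beta schedule, an MLP denoiser with a sinusoidal time
embedding predicting the added noise under mean-squared error, ancestral
sampling.

All randomness flows through an explicit ``numpy`` generator stored on the
state, so training is bit-reproducible and resumable: calling ``train`` for
one epoch R times is identical to calling it once for R epochs, which is what
makes single-node federation exactly equivalent to centralized training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .fixtures import CATEGORICAL, CONTINUOUS, ClinicalTable, TableSchema
from .preprocess import Transformer, inverse_transform, transform

__all__ = [
    "CTGANConfig",
    "DiffusionConfig",
    "GeneratorState",
    "init_state",
    "train",
    "train_ctgan",
    "train_diffusion",
    "sample",
    "get_weights",
    "set_weights",
]


@dataclass(frozen=True)
class CTGANConfig:
    generator_hidden: tuple[int, int] = (256, 256)
    discriminator_hidden: tuple[int, int] = (256, 256)
    lr: float = 2e-4
    weight_decay: float = 1e-6
    batch_size: int = 500
    embedding_dim: int = 128
    pac: int = 10
    epochs: int = 500
    gp_lambda: float = 10.0
    gumbel_tau: float = 0.2
    dropout: float = 0.5
    adam_betas: tuple[float, float] = (0.5, 0.9)

    def __post_init__(self):
        if self.batch_size % self.pac != 0:
            raise ValueError("batch_size must be divisible by pac")
        if min(self.lr, self.weight_decay, self.batch_size) <= 0:
            raise ValueError("rates must be positive")


@dataclass(frozen=True)
class DiffusionConfig:
    T: int = 500
    mlp_hidden: tuple[int, int] = (512, 512)
    lr: float = 1e-4
    batch_size: int = 500
    beta_start: float = 1e-4
    beta_end: float = 0.02
    epochs: int = 500
    time_embed_dim: int = 16
    lr_schedule_total: int | None = None  # linear decay horizon in epochs; None = constant

    def __post_init__(self):
        if not (0 < self.beta_start < self.beta_end < 1):
            raise ValueError("need 0 < beta_start < beta_end < 1")
        if self.T < 1:
            raise ValueError("T must be >= 1")


def beta_schedule(cfg: DiffusionConfig) -> np.ndarray:
    return np.linspace(cfg.beta_start, cfg.beta_end, cfg.T)


class _MLP:
    def __init__(self, n_in: int, hidden: tuple[int, ...], n_out: int,
                 rng: np.random.Generator):
        dims = [n_in, *hidden, n_out]
        self.layers = [ad.Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def parameters(self) -> list[ad.Tensor]:
        return [p for l in self.layers for p in l.parameters()]


class _ResidualGenerator:
    """CTGAN-style generator: residual blocks (Linear + BatchNorm + ReLU,
    output concatenated onto the block input) followed by a linear head."""

    def __init__(self, n_in: int, hidden: tuple[int, ...], n_out: int,
                 rng: np.random.Generator):
        self.blocks = []
        dim = n_in
        for h in hidden:
            self.blocks.append((ad.Linear(dim, h, rng), ad.BatchNorm(h)))
            dim += h
        self.head = ad.Linear(dim, n_out, rng)

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        h = x
        for lin, bn in self.blocks:
            out = ad.relu(bn(lin(h)))
            h = ad.concat([h, out], axis=1)
        return self.head(h)

    def parameters(self) -> list[ad.Tensor]:
        out = []
        for lin, bn in self.blocks:
            out.extend(lin.parameters())
            out.extend(bn.parameters())
        out.extend(self.head.parameters())
        return out


@dataclass
class GeneratorState:
    """Trainable model state with a flat-weight view for federated averaging.

    ``get_weights``/``set_weights`` expose every trainable parameter as one
    ordered float64 vector (generator layers first, then the critic for the
    GAN; denoiser layers for the diffusion model), ravelled in layer order
    (W then b).  The ordering is fixed at construction and stable across
    processes.
    """

    kind: str
    config: CTGANConfig | DiffusionConfig
    transformer: Transformer
    schema: TableSchema
    rng: np.random.Generator
    nets: dict = field(default_factory=dict)
    optimizers: dict = field(default_factory=dict)
    cond_freqs: list[np.ndarray] = field(default_factory=list)
    epochs_done: int = 0
    trained: bool = False

    def _params(self) -> list[ad.Tensor]:
        out = []
        for key in sorted(self.nets):
            out.extend(self.nets[key].parameters())
        return out


def _cond_layout(tr: Transformer) -> list[tuple[str, int]]:
    return [(c.name, len(c.labels)) for c in tr.columns if c.kind == CATEGORICAL]


def init_state(
    kind: str,
    transformer: Transformer,
    schema: TableSchema,
    config: CTGANConfig | DiffusionConfig | None = None,
    seed: int = 0,
) -> GeneratorState:
    """Build a fresh, deterministic model state."""
    rng = np.random.default_rng(seed)
    d = transformer.output_width
    if kind == "ctgan":
        cfg = config or CTGANConfig()
        cond_dim = sum(k for _, k in _cond_layout(transformer))
        g = _ResidualGenerator(cfg.embedding_dim + cond_dim, cfg.generator_hidden, d, rng)
        disc = _MLP(cfg.pac * (d + cond_dim), cfg.discriminator_hidden, 1, rng)
        nets = {"g": g, "h_disc": disc}
        opts = {
            "g": ad.Adam(g.parameters(), cfg.lr, cfg.adam_betas,
                         weight_decay=cfg.weight_decay),
            "h_disc": ad.Adam(disc.parameters(), cfg.lr, cfg.adam_betas,
                              weight_decay=cfg.weight_decay),
        }
    elif kind == "diffusion":
        cfg = config or DiffusionConfig()
        net = _MLP(d + cfg.time_embed_dim, cfg.mlp_hidden, d, rng)
        nets = {"eps": net}
        opts = {"eps": ad.Adam(net.parameters(), cfg.lr)}
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    freqs = [np.full(k, 1.0 / k) for _, k in _cond_layout(transformer)]
    return GeneratorState(kind, cfg, transformer, schema, rng, nets, opts, freqs)


# --------------------------------------------------------------------------
# Weight-vector view
# --------------------------------------------------------------------------


def get_weights(state: GeneratorState) -> np.ndarray:
    return np.concatenate([p.data.ravel() for p in state._params()])


def set_weights(state: GeneratorState, v: np.ndarray) -> GeneratorState:
    v = np.asarray(v, dtype=np.float64)
    params = state._params()
    total = sum(p.data.size for p in params)
    if v.size != total:
        raise ValueError(f"weight vector length {v.size} != {total}")
    pos = 0
    for p in params:
        p.data[...] = v[pos:pos + p.data.size].reshape(p.data.shape)
        pos += p.data.size
    return state


# --------------------------------------------------------------------------
# CTGAN internals
# --------------------------------------------------------------------------


def _gumbel_softmax(logits: ad.Tensor, tau: float, rng: np.random.Generator) -> ad.Tensor:
    u = rng.random(logits.shape).clip(1e-12, 1 - 1e-12)
    g = -np.log(-np.log(u))
    return ad.softmax((logits + ad.Tensor(g)) * (1.0 / tau), axis=1)


def _apply_output_activation(raw: ad.Tensor, tr: Transformer, tau: float,
                             rng: np.random.Generator) -> ad.Tensor:
    """tanh on normalized scalars, gumbel-softmax on one-hot blocks."""
    pieces = []
    for (start, stop), ct in zip(tr.spans(), tr.columns):
        if ct.kind == CONTINUOUS:
            pieces.append(ad.tanh(ad.slice_cols(raw, start, start + 1)))
            pieces.append(_gumbel_softmax(ad.slice_cols(raw, start + 1, stop), tau, rng))
        else:
            pieces.append(_gumbel_softmax(ad.slice_cols(raw, start, stop), tau, rng))
    return ad.concat(pieces, axis=1)


def _log_softmax(a: ad.Tensor) -> ad.Tensor:
    shift = a.data.max(axis=1, keepdims=True)
    e = ad.exp(a - ad.Tensor(shift))
    lse = ad.log(ad.sum_(e, axis=1, keepdims=True)) + ad.Tensor(shift)
    return a - lse


class _CondSampler:
    """Training-by-sampling: pick a categorical column uniformly, a level by
    log-frequency, and a real row that carries that level."""

    def __init__(self, table: ClinicalTable, tr: Transformer):
        self.layout = _cond_layout(tr)
        self.cond_dim = sum(k for _, k in self.layout)
        self.n_rows = len(table)
        self.offsets = np.cumsum([0] + [k for _, k in self.layout])
        self.row_index: list[list[np.ndarray]] = []
        self.log_freqs: list[np.ndarray] = []
        self.freqs: list[np.ndarray] = []
        self._cum_lf: list[np.ndarray] = []
        self._rows_flat: list[np.ndarray] = []
        self._level_off: list[np.ndarray] = []
        self._level_cnt: list[np.ndarray] = []
        for name, k in self.layout:
            codes = table.df[name].to_numpy(int)
            counts = np.bincount(codes, minlength=k).astype(float)
            index = [np.flatnonzero(codes == lev) for lev in range(k)]
            self.row_index.append(index)
            freq = counts / counts.sum()
            self.freqs.append(freq)
            lf = np.log(counts + 1.0)
            self.log_freqs.append(lf / lf.sum())
            self._cum_lf.append(np.cumsum(lf / lf.sum()))
            self._rows_flat.append(np.concatenate(index) if len(codes) else np.array([], int))
            self._level_cnt.append(counts.astype(int))
            self._level_off.append(np.concatenate([[0], np.cumsum(counts.astype(int))[:-1]]))

    def draw(self, m: int, rng: np.random.Generator):
        n_cat = len(self.layout)
        if n_cat == 0:  # no categorical columns: unconditional GAN
            return (np.zeros((m, 0)), np.zeros((m, 0)),
                    np.full(m, -1), np.zeros(m, dtype=int),
                    rng.integers(0, self.n_rows, size=m))
        cols = rng.integers(0, n_cat, size=m)
        cond = np.zeros((m, self.cond_dim))
        mask = np.zeros((m, n_cat))
        levels = np.zeros(m, dtype=int)
        rows = np.zeros(m, dtype=int)
        for ci in range(n_cat):
            sel = np.flatnonzero(cols == ci)
            if len(sel) == 0:
                continue
            # log-frequency level draw; zero-count levels have zero mass
            levs = np.searchsorted(self._cum_lf[ci], rng.random(len(sel)), side="right")
            levs = np.minimum(levs, len(self._cum_lf[ci]) - 1)
            levels[sel] = levs
            mask[sel, ci] = 1.0
            cond[sel, self.offsets[ci] + levs] = 1.0
            pick = (rng.random(len(sel)) * self._level_cnt[ci][levs]).astype(int)
            rows[sel] = self._rows_flat[ci][self._level_off[ci][levs] + pick]
        return cond, mask, cols, levels, rows


def _dropout(x: ad.Tensor, p: float, rng: np.random.Generator) -> ad.Tensor:
    if p <= 0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * ad.Tensor(mask)


def _run_disc(state: GeneratorState, xc: ad.Tensor) -> ad.Tensor:
    cfg = state.config
    layers = state.nets["h_disc"].layers
    h = xc
    for l in layers[:-1]:
        h = _dropout(ad.leaky_relu(l(h), 0.2), cfg.dropout, state.rng)
    return layers[-1](h)


def _run_gen(state: GeneratorState, z: np.ndarray, cond: np.ndarray) -> ad.Tensor:
    return state.nets["g"](ad.Tensor(np.concatenate([z, cond], axis=1)))


def train_ctgan(
    state: GeneratorState,
    table: ClinicalTable,
    tr: Transformer,
    epochs: int,
    seed: int | None = None,
) -> GeneratorState:
    """One critic and one generator update per step, Wasserstein loss with
    gradient penalty on pac-grouped inputs, conditional cross-entropy on the
    generator."""
    if state.kind != "ctgan":
        raise ValueError("state is not a ctgan state")
    if len(table) == 0:
        raise ValueError("empty training table")
    if epochs < 1:
        warnings.warn("epochs < 1: training skipped")
        return state
    if seed is not None:
        state.rng = np.random.default_rng(seed)
    cfg = state.config
    # fixed encode seed: every (re-)entry into training sees the same encoding,
    # so chunked training is identical to one long run
    enc = transform(table, tr, seed=0).data
    sampler = _CondSampler(table, tr)
    state.cond_freqs = sampler.freqs
    n = len(table)
    bs = min(cfg.batch_size, (n // cfg.pac) * cfg.pac)
    bs = max(cfg.pac, bs)
    steps = max(1, n // bs)
    d = enc.shape[1]
    g_params = state.nets["g"].parameters()
    d_params = state.nets["h_disc"].parameters()

    for _ in range(epochs):
        for _ in range(steps):
            # ---- critic update
            cond, _, _, _, rows = sampler.draw(bs, state.rng)
            z = state.rng.standard_normal((bs, cfg.embedding_dim))
            fake = _apply_output_activation(
                _run_gen(state, z, cond), tr, cfg.gumbel_tau, state.rng)
            fake_c = ad.concat([fake, ad.Tensor(cond)], axis=1)
            real_c = ad.Tensor(np.concatenate([enc[rows], cond], axis=1))
            groups = bs // cfg.pac
            width = cfg.pac * (d + sampler.cond_dim)
            y_fake = _run_disc(state, ad.reshape(fake_c, (groups, width)))
            y_real = _run_disc(state, ad.reshape(real_c, (groups, width)))
            # gradient penalty on per-group interpolates
            eps = state.rng.random((groups, 1))
            interp = (eps * real_c.data.reshape(groups, width)
                      + (1 - eps) * fake_c.data.reshape(groups, width))
            x_hat = ad.Tensor(interp, requires_grad=True)
            y_hat = _run_disc(state, x_hat)
            gx, = ad.grad(ad.sum_(y_hat), [x_hat], create_graph=True)
            norm = ad.sqrt(ad.sum_(gx * gx, axis=1) + 1e-12)
            gp = ad.mean((norm - 1.0) ** 2) * cfg.gp_lambda
            d_loss = ad.mean(y_fake) - ad.mean(y_real) + gp
            state.optimizers["h_disc"].step(ad.grad(d_loss, d_params))

            # ---- generator update
            cond, mask, cols, levels, _ = sampler.draw(bs, state.rng)
            z = state.rng.standard_normal((bs, cfg.embedding_dim))
            raw = _run_gen(state, z, cond)
            fake = _apply_output_activation(raw, tr, cfg.gumbel_tau, state.rng)
            fake_c = ad.concat([fake, ad.Tensor(cond)], axis=1)
            y_fake = _run_disc(state, ad.reshape(fake_c, (groups, width)))
            # cross-entropy between the conditioning vector and the raw
            # logits of the conditioned categorical block, per row
            ce_terms = []
            cat_i = 0
            for (start, stop), ct in zip(tr.spans(), tr.columns):
                if ct.kind != CATEGORICAL:
                    continue
                sel = cols == cat_i
                if sel.any():
                    tgt = np.zeros((bs, stop - start))
                    tgt[sel, levels[sel]] = 1.0
                    logsm = _log_softmax(ad.slice_cols(raw, start, stop))
                    ce_terms.append(ad.sum_(ad.Tensor(-tgt) * logsm))
                cat_i += 1
            ce = ad.Tensor(0.0)
            for t in ce_terms:
                ce = ce + t
            g_loss = -ad.mean(y_fake) + ce * (1.0 / bs)
            state.optimizers["g"].step(ad.grad(g_loss, g_params))
        state.epochs_done += 1
    state.trained = True
    return state


# --------------------------------------------------------------------------
# Diffusion internals
# --------------------------------------------------------------------------


def _time_embedding(t: np.ndarray, T: int, dim: int) -> np.ndarray:
    half = dim // 2
    freqs = np.exp(np.linspace(0, np.log(1000.0), half))
    ang = (t[:, None] / T) * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


def _run_denoiser(state: GeneratorState, x: np.ndarray | ad.Tensor,
                  t: np.ndarray) -> ad.Tensor:
    cfg = state.config
    temb = _time_embedding(t, cfg.T, cfg.time_embed_dim)
    xt = x if isinstance(x, ad.Tensor) else ad.Tensor(x)
    h = ad.concat([xt, ad.Tensor(temb)], axis=1)
    layers = state.nets["eps"].layers
    for l in layers[:-1]:
        h = ad.relu(l(h))
    return layers[-1](h)


def train_diffusion(
    state: GeneratorState,
    table: ClinicalTable,
    tr: Transformer,
    epochs: int,
    seed: int | None = None,
) -> GeneratorState:
    """DDPM training: forward-noise encoded rows with the linear beta
    schedule and regress the injected noise under mean-squared error."""
    if state.kind != "diffusion":
        raise ValueError("state is not a diffusion state")
    if len(table) == 0:
        raise ValueError("empty training table")
    if epochs < 1:
        warnings.warn("epochs < 1: training skipped")
        return state
    if seed is not None:
        state.rng = np.random.default_rng(seed)
    cfg = state.config
    enc = transform(table, tr, seed=0).data
    sampler = _CondSampler(table, tr)
    state.cond_freqs = sampler.freqs
    betas = beta_schedule(cfg)
    abar = np.cumprod(1.0 - betas)
    n, d = enc.shape
    bs = min(cfg.batch_size, n)
    steps = max(1, n // bs)
    params = state.nets["eps"].parameters()
    opt = state.optimizers["eps"]
    for _ in range(epochs):
        if cfg.lr_schedule_total:
            frac = min(state.epochs_done / cfg.lr_schedule_total, 0.99)
            opt.lr = cfg.lr * (1.0 - frac)
        perm = state.rng.permutation(n)
        for s in range(steps):
            idx = perm[s * bs:(s + 1) * bs]
            x0 = enc[idx]
            t = state.rng.integers(0, cfg.T, size=len(idx))
            noise = state.rng.standard_normal(x0.shape)
            x_t = (np.sqrt(abar[t])[:, None] * x0
                   + np.sqrt(1 - abar[t])[:, None] * noise)
            pred = _run_denoiser(state, x_t, t)
            loss = ad.mean((pred - ad.Tensor(noise)) ** 2)
            opt.step(ad.grad(loss, params))
        state.epochs_done += 1
    state.trained = True
    return state


def train(state: GeneratorState, table: ClinicalTable, tr: Transformer,
          epochs: int, seed: int | None = None) -> GeneratorState:
    """Dispatch to the state's model kind."""
    fn = train_ctgan if state.kind == "ctgan" else train_diffusion
    return fn(state, table, tr, epochs, seed)


# --------------------------------------------------------------------------
# Sampling
# --------------------------------------------------------------------------


def _sample_cond(state: GeneratorState, m: int, rng: np.random.Generator) -> np.ndarray:
    layout = _cond_layout(state.transformer)
    offsets = np.cumsum([0] + [k for _, k in layout])
    cond = np.zeros((m, int(offsets[-1])))
    if not layout:
        return cond
    cols = rng.integers(0, len(layout), size=m)
    for i in range(m):
        freq = state.cond_freqs[cols[i]]
        lev = rng.choice(len(freq), p=freq)
        cond[i, offsets[cols[i]] + lev] = 1.0
    return cond


def sample(state: GeneratorState, m: int, seed: int = 0) -> ClinicalTable:
    """Generate ``m`` records and decode them to a schema-valid table."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    tr = state.transformer
    if state.kind == "ctgan":
        cfg = state.config
        cond = _sample_cond(state, m, rng)
        z = rng.standard_normal((m, cfg.embedding_dim))
        out = _apply_output_activation(_run_gen(state, z, cond), tr,
                                       cfg.gumbel_tau, rng)
        enc = out.data
    else:
        cfg = state.config
        betas = beta_schedule(cfg)
        alphas = 1.0 - betas
        abar = np.cumprod(alphas)
        x = rng.standard_normal((m, tr.output_width))
        for t in range(cfg.T - 1, -1, -1):
            eps = _run_denoiser(state, x, np.full(m, t)).data
            coef = (1 - alphas[t]) / np.sqrt(1 - abar[t])
            x = (x - coef * eps) / np.sqrt(alphas[t])
            if t > 0:
                x = x + np.sqrt(betas[t]) * rng.standard_normal(x.shape)
        # clip normalized scalars to the valid range before decoding
        for (start, stop), ct in zip(tr.spans(), tr.columns):
            if ct.kind == CONTINUOUS:
                x[:, start] = np.clip(x[:, start], -1.0, 1.0)
        enc = x
    table = inverse_transform(enc, tr, state.schema)
    table.validate()
    return table
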
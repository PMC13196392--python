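"""Compact numpy neural-network core for the fragility classifier.

Implements a pooling-token-mixer (MetaFormer-style) image backbone with two
parallel 16-unit fully-connected heads and a fusion layer, together with the
exact forward/backward passes needed for SGD-with-momentum training and
Grad-CAM attribution.  No attention anywhere: token mixing is a 3×3 mean
pool minus identity, which is linear and self-adjoint, so its backward pass
is the same pooling applied to the incoming gradient.

Shapes: images enter as (B, S, S) grey arrays in [0, 1]; tokens live as
(B, nH, nW, C).  All parameters sit in a flat dict name → ndarray, so the
optimiser and checkpointing stay trivial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import erf

Params = Dict[str, np.ndarray]

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * phi


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def pool3x3(x: np.ndarray) -> np.ndarray:
    """Mean 3×3 spatial pooling with zero padding on (B, H, W, C) tokens.

    Symmetric kernel + zero padding make this operator self-adjoint; the
    backward pass reuses it directly.
    """
    B, H, W, C = x.shape
    padded = np.zeros((B, H + 2, W + 2, C), dtype=x.dtype)
    padded[:, 1:-1, 1:-1] = x
    out = np.zeros_like(x)
    for dr in range(3):
        for dc in range(3):
            out += padded[:, dr : dr + H, dc : dc + W]
    return out / 9.0


def _layernorm_forward(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float = 1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_backward(dy: np.ndarray, cache) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    xhat, inv, g = cache
    C = xhat.shape[-1]
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv / C * (C * dxhat - dxhat.sum(axis=-1, keepdims=True) - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True))
    return dx, dg, db


@dataclass(frozen=True)
class ArchConfig:
    """Backbone geometry; the full-size profile mirrors PoolFormer-s12 scales,
    the desk profile keeps training tractable on one CPU.

    Inputs carry ``in_channels`` image planes: at desk scale the ROI enters
    as a downscaled whole-ROI context plane (carrying bone/soft-tissue
    contrast) plus a native-resolution centre crop (carrying trabecular
    texture that whole-ROI downscaling would destroy)."""

    input_size: int = 64
    patch_size: int = 8
    in_channels: int = 2
    embed_dim: int = 32
    depth: int = 2
    mlp_ratio: int = 2
    head_width: int = 16  # the two parallel heads are exactly this wide
    n_engineered: int = 17  # age, sex, 2 missing flags, raw_tbs, 12 GLCM

    def __post_init__(self) -> None:
        if self.input_size % self.patch_size != 0:
            raise ValueError("input_size must be divisible by patch_size")

    @property
    def tokens_per_side(self) -> int:
        return self.input_size // self.patch_size


def init_params(cfg: ArchConfig, seed: int = 0, head_width_override: Optional[int] = None) -> Params:
    """He/Glorot-style initialisation, fully determined by the seed."""
    rng = np.random.default_rng(seed)
    hw = head_width_override if head_width_override is not None else cfg.head_width
    C, R = cfg.embed_dim, cfg.embed_dim * cfg.mlp_ratio
    p: Params = {}

    def dense(name, fan_in, fan_out):
        p[f"{name}.W"] = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        p[f"{name}.b"] = np.zeros(fan_out)

    dense("embed", cfg.in_channels * cfg.patch_size**2, C)
    for d in range(cfg.depth):
        p[f"blk{d}.ln1.g"] = np.ones(C)
        p[f"blk{d}.ln1.b"] = np.zeros(C)
        p[f"blk{d}.ln2.g"] = np.ones(C)
        p[f"blk{d}.ln2.b"] = np.zeros(C)
        dense(f"blk{d}.mlp1", C, R)
        dense(f"blk{d}.mlp2", R, C)
    p["final_ln.g"] = np.ones(C)
    p["final_ln.b"] = np.zeros(C)
    dense("headA.fc", C, hw)
    dense("headA.out", hw, 1)
    dense("headB.fc", C, hw)
    dense("headB.out", hw, 1)
    dense("fusion", 2 * hw + cfg.n_engineered, 2)
    return p


class PoolMixerNet:
    """Dual-head pooling-token-mixer classifier with engineered-feature fusion.

    Head A is supervised for osteoporosis, head B for degraded TBS; their
    16-unit ReLU activations (not the head logits) are concatenated with the
    standardised engineered features and mapped to the 2-way softmax for
    very-high-bone-fragility.
    """

    def __init__(self, cfg: ArchConfig, seed: int = 0, head_width_override: Optional[int] = None):
        self.cfg = cfg
        self.head_width = head_width_override if head_width_override is not None else cfg.head_width
        self.params = init_params(cfg, seed=seed, head_width_override=head_width_override)
        self.seed = seed

    # -- forward ----------------------------------------------------------

    def _patchify(self, x: np.ndarray) -> np.ndarray:
        B, C = x.shape[0], self.cfg.in_channels
        S, P = self.cfg.input_size, self.cfg.patch_size
        n = self.cfg.tokens_per_side
        return (
            x.reshape(B, C, n, P, n, P).transpose(0, 2, 4, 1, 3, 5).reshape(B, n, n, C * P * P)
        )

    def forward(self, images: np.ndarray, engineered: np.ndarray, want_cache: bool = False):
        """Full forward pass.

        Returns a dict with ``probs`` (B, 2), ``p_headA``/``p_headB`` (B,),
        ``tokens`` (final token-mixing stage activations, for Grad-CAM) and,
        when ``want_cache``, the caches needed for the backward pass.
        """
        p = self.params
        x = np.asarray(images, dtype=float)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3 and self.cfg.in_channels == 1:
            x = x[:, None]
        elif x.ndim == 3:
            x = x[None]
        eng = np.atleast_2d(np.asarray(engineered, dtype=float))
        cache: Dict[str, object] = {}
        patches = self._patchify(x - 0.5)
        t = patches @ p["embed.W"] + p["embed.b"]
        cache["patches"] = patches
        blocks = []
        for d in range(self.cfg.depth):
            u, ln1c = _layernorm_forward(t, p[f"blk{d}.ln1.g"], p[f"blk{d}.ln1.b"])
            mixed = pool3x3(u) - u
            y = t + mixed
            v, ln2c = _layernorm_forward(y, p[f"blk{d}.ln2.g"], p[f"blk{d}.ln2.b"])
            a1 = v @ p[f"blk{d}.mlp1.W"] + p[f"blk{d}.mlp1.b"]
            h1 = gelu(a1)
            z = y + h1 @ p[f"blk{d}.mlp2.W"] + p[f"blk{d}.mlp2.b"]
            blocks.append({"ln1c": ln1c, "ln2c": ln2c, "v": v, "a1": a1, "h1": h1})
            t = z
        tokens = t  # final token-mixing stage output (B, n, n, C)
        fin, finc = _layernorm_forward(tokens, p["final_ln.g"], p["final_ln.b"])
        f = fin.mean(axis=(1, 2))  # GAP
        aA = f @ p["headA.fc.W"] + p["headA.fc.b"]
        hA = np.maximum(aA, 0.0)
        logitA = (hA @ p["headA.out.W"] + p["headA.out.b"])[:, 0]
        aB = f @ p["headB.fc.W"] + p["headB.fc.b"]
        hB = np.maximum(aB, 0.0)
        logitB = (hB @ p["headB.out.W"] + p["headB.out.b"])[:, 0]
        fused = np.concatenate([hA, hB, eng], axis=1)
        logits = fused @ p["fusion.W"] + p["fusion.b"]
        out = {
            "probs": softmax(logits),
            "logits": logits,
            "p_headA": sigmoid(logitA),
            "p_headB": sigmoid(logitB),
            "tokens": tokens,
            "head_activations": (hA, hB),
        }
        if want_cache:
            cache.update(
                blocks=blocks, finc=finc, fin=fin, f=f, aA=aA, hA=hA, aB=aB, hB=hB,
                fused=fused, eng=eng, logitA=logitA, logitB=logitB,
            )
            out["cache"] = cache
        return out

    # -- backward ---------------------------------------------------------

    def backward(
        self,
        cache: Dict[str, object],
        d_logits: np.ndarray,
        d_logitA: Optional[np.ndarray] = None,
        d_logitB: Optional[np.ndarray] = None,
        want_token_grad: bool = False,
    ):
        """Backpropagate given output-side gradients; returns (grads, d_tokens)."""
        p = self.params
        g: Params = {k: np.zeros_like(v) for k, v in p.items()}
        fused = cache["fused"]
        g["fusion.W"] = fused.T @ d_logits
        g["fusion.b"] = d_logits.sum(axis=0)
        d_fused = d_logits @ p["fusion.W"].T
        hw = self.head_width
        d_hA = d_fused[:, :hw].copy()
        d_hB = d_fused[:, hw : 2 * hw].copy()

        hA, hB, aA, aB, f = cache["hA"], cache["hB"], cache["aA"], cache["aB"], cache["f"]
        if d_logitA is not None:
            g["headA.out.W"] = hA.T @ d_logitA[:, None]
            g["headA.out.b"] = np.array([d_logitA.sum()])
            d_hA += d_logitA[:, None] @ p["headA.out.W"].T
        if d_logitB is not None:
            g["headB.out.W"] = hB.T @ d_logitB[:, None]
            g["headB.out.b"] = np.array([d_logitB.sum()])
            d_hB += d_logitB[:, None] @ p["headB.out.W"].T
        d_aA = d_hA * (aA > 0)
        d_aB = d_hB * (aB > 0)
        g["headA.fc.W"] = f.T @ d_aA
        g["headA.fc.b"] = d_aA.sum(axis=0)
        g["headB.fc.W"] = f.T @ d_aB
        g["headB.fc.b"] = d_aB.sum(axis=0)
        d_f = d_aA @ p["headA.fc.W"].T + d_aB @ p["headB.fc.W"].T

        n = self.cfg.tokens_per_side
        d_fin = np.broadcast_to(d_f[:, None, None, :], cache["fin"].shape) / (n * n)
        d_tokens, dg_, db_ = _layernorm_backward(np.ascontiguousarray(d_fin), cache["finc"])
        g["final_ln.g"], g["final_ln.b"] = dg_, db_

        dt = d_tokens
        for d in reversed(range(self.cfg.depth)):
            blk = cache["blocks"][d]
            # z = y + gelu(v W1 + b1) W2 + b2
            d_h1 = dt @ p[f"blk{d}.mlp2.W"].T
            g[f"blk{d}.mlp2.W"] = blk["h1"].reshape(-1, blk["h1"].shape[-1]).T @ dt.reshape(-1, dt.shape[-1])
            g[f"blk{d}.mlp2.b"] = dt.sum(axis=(0, 1, 2))
            d_a1 = d_h1 * gelu_grad(blk["a1"])
            g[f"blk{d}.mlp1.W"] = blk["v"].reshape(-1, blk["v"].shape[-1]).T @ d_a1.reshape(-1, d_a1.shape[-1])
            g[f"blk{d}.mlp1.b"] = d_a1.sum(axis=(0, 1, 2))
            d_v = d_a1 @ p[f"blk{d}.mlp1.W"].T
            d_y_ln, dg2, db2 = _layernorm_backward(d_v, blk["ln2c"])
            g[f"blk{d}.ln2.g"], g[f"blk{d}.ln2.b"] = dg2, db2
            d_y = dt + d_y_ln
            # y = t + pool(u) - u, u = LN1(t)
            d_u = pool3x3(d_y) - d_y  # self-adjoint mixer
            d_t_ln, dg1, db1 = _layernorm_backward(d_u, blk["ln1c"])
            g[f"blk{d}.ln1.g"], g[f"blk{d}.ln1.b"] = dg1, db1
            dt = d_y + d_t_ln

        patches = cache["patches"]
        g["embed.W"] = patches.reshape(-1, patches.shape[-1]).T @ dt.reshape(-1, dt.shape[-1])
        g["embed.b"] = dt.sum(axis=(0, 1, 2))
        return g, (d_tokens if want_token_grad else None)

    # -- losses -----------------------------------------------------------

    def loss_and_grads(
        self,
        images: np.ndarray,
        engineered: np.ndarray,
        y_vhbf: np.ndarray,
        y_osteo: np.ndarray,
        y_degraded: np.ndarray,
        aux_weight: float = 0.5,
    ) -> Tuple[float, Params]:
        """Total loss = CE(very-high softmax) + aux_weight·(BCE head A + BCE head B)."""
        out = self.forward(images, engineered, want_cache=True)
        cache = out["cache"]
        B = out["probs"].shape[0]
        y = np.asarray(y_vhbf, dtype=int)
        probs = out["probs"]
        eps = 1e-12
        ce = -np.log(probs[np.arange(B), y] + eps).mean()
        pA, pB = out["p_headA"], out["p_headB"]
        yA = np.asarray(y_osteo, dtype=float)
        yB = np.asarray(y_degraded, dtype=float)
        bceA = -(yA * np.log(pA + eps) + (1 - yA) * np.log(1 - pA + eps)).mean()
        bceB = -(yB * np.log(pB + eps) + (1 - yB) * np.log(1 - pB + eps)).mean()
        loss = float(ce + aux_weight * (bceA + bceB))
        d_logits = probs.copy()
        d_logits[np.arange(B), y] -= 1.0
        d_logits /= B
        d_logitA = aux_weight * (pA - yA) / B
        d_logitB = aux_weight * (pB - yB) / B
        grads, _ = self.backward(cache, d_logits, d_logitA, d_logitB)
        return loss, grads

    # -- Grad-CAM ---------------------------------------------------------

    def spatial_activations_and_grad(
        self, image: np.ndarray, engineered: np.ndarray, target_class: int = 1
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Final token-mixing stage activations and d(logit_target)/d(activations)."""
        out = self.forward(image, engineered, want_cache=True)
        d_logits = np.zeros_like(out["logits"])
        d_logits[:, int(target_class)] = 1.0
        _, d_tokens = self.backward(out["cache"], d_logits, want_token_grad=True)
        return out["tokens"][0], d_tokens[0]

    # -- persistence ------------------------------------------------------

    def state_dict(self) -> Params:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: Params) -> None:
        self.params = {k: v.copy() for k, v in state.items()}


class SGD:
    """Plain SGD with momentum and (coupled) weight decay."""

    def __init__(self, params: Params, lr: float, momentum: float = 0.9, weight_decay: float = 1e-4):
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity: Params = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Params, grads: Params) -> None:
        for k, v in params.items():
            g = grads[k] + self.weight_decay * v
            self.velocity[k] = self.momentum * self.velocity[k] - self.lr * g
            v += self.velocity[k]
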
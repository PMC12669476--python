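"""Conditional-GAN virtual staining (pix2pix-style).

A U-Net generator translates a normalised phase patch into an RGB H&E-like
image; a patch-based critic discriminates (phase, rgb) pairs. The training
objective is the conditional-GAN game with an L1 consistency term::

    G* = arg min_G max_D  L_cGAN(G, D) + lambda * L_L1(G),   lambda = 100

Training alternates single Adam steps on D and G per sample, with random
crop-jitter and mirror augmentation. Inference on large phase fields is
tiled with overlap-blend stitching so memory stays bounded and seams stay
below the blending tolerance.

The network is sized by ``patch_size`` (a power of two; the U-Net depth is
log2(patch_size) so the bottleneck is 1x1 on training patches) and
``base_width``. Defaults follow the pix2pix convention (256-px patches,
width 64); the smoke preset used throughout the test suite shrinks both so
a 16-pair overfit run takes minutes on one CPU.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .register import PatchPair

__all__ = [
    "VSModelConfig",
    "TrainReport",
    "VSModel",
    "UNetGenerator",
    "PatchDiscriminator",
    "loss_terms",
    "train",
    "stain",
]


@dataclass
class VSModelConfig:
    patch_size: int = 256
    base_width: int = 64
    disc_width: int = 64
    lambda_l1: float = 100.0
    epochs: int = 100
    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    jitter_px: int = 30  # resize-and-crop jitter amplitude
    mirror: bool = True
    tile_size: int = 1024
    tile_overlap: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be non-negative")
        if self.patch_size & (self.patch_size - 1):
            raise ValueError("patch_size must be a power of two")
        if self.tile_size % (1 << self.depth):
            raise ValueError("tile_size must be a multiple of the generator "
                             f"downsampling factor {1 << self.depth}")

    @property
    def depth(self) -> int:
        return int(np.log2(self.patch_size))

    @classmethod
    def smoke(cls, seed: int = 0, epochs: int = 50) -> "VSModelConfig":
        """Desk-scale preset: 64-px patches, width 8, minutes on one CPU."""
        return cls(patch_size=64, base_width=8, disc_width=8, epochs=epochs,
                   jitter_px=8, tile_size=64, seed=seed)


@dataclass
class TrainReport:
    g_l1: list[float] = field(default_factory=list)
    g_adv: list[float] = field(default_factory=list)
    d_loss: list[float] = field(default_factory=list)
    wall_clock_s: float = 0.0
    seed: int = 0
    config: dict = field(default_factory=dict)


class UNetGenerator(_nn.Module):
    """U-Net with ``depth`` stride-2 encoder/decoder levels and skip concats."""

    MAX_MULT = 8

    def __init__(self, depth: int, base: int, c_in: int = 1, c_out: int = 3, rng=None):
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        ch = [min(base * 2**i, base * self.MAX_MULT) for i in range(depth)]
        self.ch = ch
        self.enc = []
        self.enc_norm = []
        self.enc_act = []
        prev = c_in
        for i in range(depth):
            self.enc.append(_nn.Conv2d(prev, ch[i], rng=rng))
            # no norm on the first level or the (1x1) bottleneck
            self.enc_norm.append(_nn.InstanceNorm(ch[i]) if 0 < i < depth - 1 else None)
            self.enc_act.append(_nn.LeakyReLU(0.2))
            prev = ch[i]
        self.dec = []
        self.dec_norm = []
        self.dec_act = []
        for i in range(depth - 2, -1, -1):
            self.dec.append(_nn.ConvTranspose2d(prev, ch[i], rng=rng))
            self.dec_norm.append(_nn.InstanceNorm(ch[i]))
            self.dec_act.append(_nn.ReLU())
            prev = ch[i] * 2  # skip concat
        self.final = _nn.ConvTranspose2d(prev, c_out, rng=rng)
        self.final_act = _nn.ReLU()
        self.tanh = _nn.Tanh()

    def _modules(self):
        return (*self.enc, *filter(None, self.enc_norm), *self.dec,
                *self.dec_norm, self.final)

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def buffers(self):
        return [b for m in self._modules() for b in m.buffers()]

    def set_training(self, flag: bool) -> None:
        for m in self._modules():
            m.set_training(flag)

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = []
        h = x
        for i in range(self.depth):
            h = self.enc[i].forward(h)
            if self.enc_norm[i] is not None:
                h = self.enc_norm[i].forward(h)
            feats.append(h)
            if i < self.depth - 1:
                h = self.enc_act[i].forward(h)
            # note: activation of the stored feature happens on the way in to
            # the next level; the raw feature is what the skip connection uses
        self._feats = feats
        h = feats[-1]
        self._splits = []
        for j, i in enumerate(range(self.depth - 2, -1, -1)):
            h = self.dec_act[j].forward(h)
            h = self.dec[j].forward(h)
            h = self.dec_norm[j].forward(h)
            h = np.concatenate([h, feats[i]], axis=1)
            self._splits.append(self.ch[i])
        h = self.final_act.forward(h)
        h = self.final.forward(h)
        return self.tanh.forward(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.tanh.backward(dout)
        d = self.final.backward(d)
        d = self.final_act.backward(d)
        dfeats = [np.zeros_like(f) for f in self._feats]
        for j in range(self.depth - 2, -1, -1):
            i = self.depth - 2 - j
            split = self._splits[j]
            d_dec, d_skip = d[:, :split], d[:, split:]
            dfeats[i] += d_skip
            d = self.dec_norm[j].backward(d_dec)
            d = self.dec[j].backward(d)
            d = self.dec_act[j].backward(d)
        dfeats[-1] += d
        d = dfeats[-1]
        for i in range(self.depth - 1, -1, -1):
            if i < self.depth - 1:
                d = self.enc_act[i].backward(d)
                d = d + dfeats[i]
            if self.enc_norm[i] is not None:
                d = self.enc_norm[i].backward(d)
            d = self.enc[i].backward(d)
        return d


class PatchDiscriminator(_nn.Sequential):
    """Patch critic over concatenated (phase, rgb) inputs (70x70-style)."""

    def __init__(self, base: int = 64, c_in: int = 4, rng=None):
        rng = rng or np.random.default_rng(1)
        super().__init__(
            _nn.Conv2d(c_in, base, rng=rng), _nn.LeakyReLU(0.2),
            _nn.Conv2d(base, base * 2, rng=rng), _nn.InstanceNorm(base * 2), _nn.LeakyReLU(0.2),
            _nn.Conv2d(base * 2, base * 4, rng=rng), _nn.InstanceNorm(base * 4), _nn.LeakyReLU(0.2),
            _nn.Conv2d(base * 4, base * 8, k=4, stride=1, pad=1, rng=rng),
            _nn.InstanceNorm(base * 8), _nn.LeakyReLU(0.2),
            _nn.Conv2d(base * 8, 1, k=4, stride=1, pad=1, rng=rng),
        )


@dataclass
class VSModel:
    generator: UNetGenerator
    discriminator: PatchDiscriminator
    config: VSModelConfig
    phase_norm: tuple[float, float]  # (1st, 99th) percentile of training phase

    def normalize_phase(self, phase: np.ndarray) -> np.ndarray:
        lo, hi = self.phase_norm
        return 2.0 * (np.asarray(phase, float) - lo) / max(hi - lo, 1e-9) - 1.0


def loss_terms(generated: np.ndarray, target: np.ndarray,
               critic_logits_fake: np.ndarray, lambda_l1: float = 100.0):
    """Generator loss decomposition: (adversarial, L1, total).

    ``total = l_cgan + lambda * l_l1`` exactly; the critic logits are those
    produced for the generated pair.
    """
    if generated.shape != target.shape:
        raise ValueError("generated/target shapes must match")
    l_cgan, _ = _nn.bce_with_logits(critic_logits_fake, 1.0)
    l_l1 = float(np.mean(np.abs(generated - target)))
    return l_cgan, l_l1, l_cgan + lambda_l1 * l_l1


def _augment(phase: np.ndarray, rgb: np.ndarray, cfg: VSModelConfig, rng):
    from skimage.transform import resize

    s = cfg.patch_size
    if cfg.jitter_px > 0:
        big = s + cfg.jitter_px
        ph = resize(phase, (big, big), order=1, anti_aliasing=False)
        im = resize(rgb, (big, big, rgb.shape[2]), order=1, anti_aliasing=False)
        oy, ox = rng.integers(0, cfg.jitter_px + 1, size=2)
        phase, rgb = ph[oy:oy + s, ox:ox + s], im[oy:oy + s, ox:ox + s]
    if cfg.mirror:
        if rng.random() < 0.5:
            phase, rgb = phase[:, ::-1], rgb[:, ::-1]
        if rng.random() < 0.5:
            phase, rgb = phase[::-1], rgb[::-1]
    return np.ascontiguousarray(phase), np.ascontiguousarray(rgb)


def train(pairs: list[PatchPair], cfg: VSModelConfig | None = None):
    """Train the virtual-staining cGAN on accepted patch pairs.

    Returns ``(model, report)``. Deterministic for a fixed seed: all
    randomness (weight init, shuffling, augmentation) flows from
    ``cfg.seed``. Patches are resized to ``cfg.patch_size`` if needed.
    """
    from skimage.transform import resize

    cfg = cfg or VSModelConfig()
    accepted = [p for p in pairs if p.accepted]
    if not accepted:
        raise ValueError("no accepted pairs to train on")
    rng = np.random.default_rng(cfg.seed)

    phases = []
    rgbs = []
    s = cfg.patch_size
    for p in accepted:
        ph = np.asarray(p.phase_patch, float)
        im = np.clip(np.asarray(p.rgb_patch, float), 0, 1)
        if ph.shape != (s, s):
            ph = resize(ph, (s, s), order=1, anti_aliasing=True)
            im = resize(im, (s, s, im.shape[2]), order=1, anti_aliasing=True)
        phases.append(ph)
        rgbs.append(im)
    lo, hi = np.percentile(np.stack(phases), [1, 99])
    model = VSModel(
        generator=UNetGenerator(cfg.depth, cfg.base_width, rng=np.random.default_rng(rng.integers(2**31))),
        discriminator=PatchDiscriminator(cfg.disc_width, rng=np.random.default_rng(rng.integers(2**31))),
        config=cfg,
        phase_norm=(float(lo), float(hi)),
    )
    G, D = model.generator, model.discriminator
    G.set_training(True)
    D.set_training(True)
    opt_g = _nn.Adam(G.params(), lr=cfg.lr, betas=cfg.betas)
    opt_d = _nn.Adam(D.params(), lr=cfg.lr, betas=cfg.betas)

    report = TrainReport(seed=cfg.seed, config=vars(cfg).copy())
    t0 = time.perf_counter()
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(accepted))
        e_l1, e_adv, e_d = [], [], []
        for idx in order:
            ph, im = _augment(phases[idx], rgbs[idx], cfg, rng)
            x = model.normalize_phase(ph)[None, None]
            y = (2.0 * im - 1.0).transpose(2, 0, 1)[None]

            y_hat = G.forward(x)

            # --- discriminator step ---
            opt_d.zero_grad()
            logits_real = D.forward(np.concatenate([x, y], axis=1))
            l_real, d_real = _nn.bce_with_logits(logits_real, 1.0)
            D.backward(0.5 * d_real)
            logits_fake = D.forward(np.concatenate([x, y_hat], axis=1))
            l_fake, d_fake = _nn.bce_with_logits(logits_fake, 0.0)
            D.backward(0.5 * d_fake)
            opt_d.step()

            # --- generator step ---
            opt_g.zero_grad()
            opt_d.zero_grad()  # D acts as a frozen critic here
            logits = D.forward(np.concatenate([x, y_hat], axis=1))
            l_adv, d_adv = _nn.bce_with_logits(logits, 1.0)
            d_input = D.backward(d_adv)
            l_l1, d_l1 = _nn.l1_loss(y_hat, y)
            G.backward(d_input[:, 1:] + cfg.lambda_l1 * d_l1)
            opt_g.step()

            e_l1.append(l_l1)
            e_adv.append(l_adv)
            e_d.append(0.5 * (l_real + l_fake))
        report.g_l1.append(float(np.mean(e_l1)))
        report.g_adv.append(float(np.mean(e_adv)))
        report.d_loss.append(float(np.mean(e_d)))
    report.wall_clock_s = time.perf_counter() - t0
    return model, report


def _infer_tile(model: VSModel, phase_norm: np.ndarray) -> np.ndarray:
    """Run the generator on one normalised tile, padded to the U-Net stride."""
    model.generator.set_training(False)
    mult = 1 << model.generator.depth
    h, w = phase_norm.shape
    ph = ((h + mult - 1) // mult) * mult
    pw = ((w + mult - 1) // mult) * mult
    # the U-Net needs spatial size >= its receptive stride
    ph, pw = max(ph, mult), max(pw, mult)
    pad = np.pad(phase_norm, ((0, ph - h), (0, pw - w)), mode="reflect") \
        if (ph, pw) != (h, w) else phase_norm
    out = model.generator.forward(pad[None, None])[0]
    return ((out + 1.0) / 2.0).transpose(1, 2, 0)[:h, :w]


def stain(model: VSModel, phase_field: np.ndarray, tile_size: int | None = None,
          overlap: int | None = None) -> np.ndarray:
    """Virtually stain a phase field; output RGB in [0, 1], same spatial size.

    Fields larger than ``tile_size`` are processed in overlapping tiles whose
    RGB outputs are blended with linear ramps (same scheme as image
    stitching), keeping seam discontinuities below the blend tolerance.
    """
    from .recon import stitch

    cfg = model.config
    tile_size = tile_size or cfg.tile_size
    overlap = cfg.tile_overlap if overlap is None else overlap
    phase_field = np.asarray(phase_field, float)
    if phase_field.ndim != 2:
        raise ValueError("phase field must be single-channel")
    x = model.normalize_phase(phase_field)
    med = np.median(np.abs(x))
    if not np.isfinite(med) or med > 10.0:
        raise ValueError("input is far outside the model's phase normalisation; "
                         "was this field produced by the same pipeline?")
    H, W = x.shape
    if H <= tile_size and W <= tile_size:
        return np.clip(_infer_tile(model, x), 0, 1)

    step = tile_size - overlap
    if step <= 0:
        raise ValueError("tile overlap must be smaller than tile size")
    ys = sorted({min(y, max(H - tile_size, 0)) for y in range(0, H, step)})
    xs = sorted({min(xx, max(W - tile_size, 0)) for xx in range(0, W, step)})
    tiles, offs = [], []
    for y in ys:
        for xx in xs:
            tiles.append(_infer_tile(model, x[y:y + tile_size, xx:xx + tile_size]))
            offs.append((y, xx))
    out = np.stack(
        [stitch([t[..., c] for t in tiles], offs) for c in range(3)], axis=-1
    )
    return np.clip(out[:H, :W], 0, 1)
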
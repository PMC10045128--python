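"""The segmentation network: a U-shaped encoder-decoder with BN-ReLU-conv
residual blocks and pooling-index transmission.

Architecture (input N x N, channel width C, constant through the net):

* Encoder — an initial 3x3 convolution lifts the single input channel to C;
  level 0 then runs two blocks (each block = batch norm -> activation -> 3x3
  conv) and adds the block output to the preserved initial-conv output
  (residual addition). Levels 1..4 each start with 2x2/stride-2 max pooling
  whose argmax indices are stored; level 1 runs two blocks, levels 2-4 run
  three, each followed by a residual addition of the pool output. A fifth
  pooling reaches N/32. Encoder totals: 14 convolutions, 5 poolings.
* Decoder — each level starts with max unpooling that scatters features back
  to the positions recorded by the paired pooling (last pool feeds the first
  unpool), concatenates with the matching encoder addition output into a 2C
  structure, reduces back to C with one block, runs three more blocks, and
  adds the reducing block's output to the third block's output. The final
  level (back at N x N) instead runs the reducing block, one block whose
  activation is a sigmoid, and a 1x1 convolution consolidating all channels;
  a sigmoid on that single channel yields the probability map. Decoder
  totals: 19 convolutions, 5 unpoolings. Grand total: 33 convolutions.

Everything runs on the NumPy engine in :mod:`ratunet.nn`; the graph is a
plain Python composition with hand-routed gradients (residual additions sum
gradients, concatenations split them).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .io_preprocess import BinaryMask, MRVolume

#: block counts per encoder level 0..4; with the initial convolution this
#: gives the 14-convolution encoder.
ENCODER_BLOCKS = (2, 2, 3, 3, 3)
N_LEVELS = 5


@dataclass(frozen=True)
class NetworkSpec:
    """Layer inventory of an instantiated network, filled by graph traversal."""

    input_size: int
    base_channels: int
    conv_count: int
    pool_count: int
    unpool_count: int
    encoder_conv_count: int
    decoder_conv_count: int
    bn_count: int
    activation_count: int


@dataclass(frozen=True)
class PoolRecord:
    """Argmax index map of one 2x2/stride-2 pooling, for index transmission."""

    level: int
    pooled_shape: tuple[int, ...]
    indices: np.ndarray  # same shape as the pooled map, values in 0..3


@dataclass(frozen=True)
class SegmentationResult:
    probability: np.ndarray  # rank-3, in [0,1]
    mask: BinaryMask
    threshold: float


def max_pool_with_indices(feature: np.ndarray, level: int = 0) -> tuple[np.ndarray, PoolRecord]:
    """2x2/stride-2 max pooling over the trailing two axes with an index record."""
    pooled, idx = nn.max_pool2x2(np.asarray(feature))
    return pooled, PoolRecord(level=level, pooled_shape=pooled.shape, indices=idx)


def max_unpool(pooled: np.ndarray, record: PoolRecord) -> np.ndarray:
    """Scatter pooled values to the recorded argmax positions; zeros elsewhere."""
    pooled = np.asarray(pooled)
    if pooled.shape != record.pooled_shape:
        raise ValueError(f"pooled shape {pooled.shape} incompatible with "
                         f"record shape {record.pooled_shape}")
    return nn.max_unpool2x2(pooled, record.indices)


class Block:
    """Batch normalization -> activation -> 3x3 same-padding convolution."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 activation: str = "relu", dtype=np.float32) -> None:
        self.bn = nn.BatchNorm2d(c_in, dtype=dtype)
        self.act = nn.Sigmoid() if activation == "sigmoid" else nn.ReLU()
        self.conv = nn.Conv2d(c_in, c_out, 3, rng, dtype=dtype)

    @property
    def layers(self) -> list[nn.Layer]:
        return [self.bn, self.act, self.conv]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return self.conv.forward(self.act.forward(self.bn.forward(x, training), training),
                                 training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.bn.backward(self.act.backward(self.conv.backward(dout)))


class RUNet:
    """The instantiated network: weights, forward/backward, and introspection."""

    def __init__(self, input_size: int, base_channels: int = 64, seed: int = 0,
                 dtype=np.float32) -> None:
        if input_size % 32 != 0 or input_size < 32:
            raise ValueError(f"input size {input_size} must be a positive multiple of 32")
        if base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        self.input_size = input_size
        self.base_channels = base_channels
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c = base_channels

        self.conv_in = nn.Conv2d(1, c, 3, rng, dtype=dtype)
        self.enc_blocks: list[list[Block]] = [
            [Block(c, c, rng, dtype=dtype) for _ in range(n)] for n in ENCODER_BLOCKS
        ]
        # decoder levels at N/16, N/8, N/4, N/2: reduce block + three blocks
        self.dec_levels: list[dict] = [
            {"reduce": Block(2 * c, c, rng, dtype=dtype),
             "blocks": [Block(c, c, rng, dtype=dtype) for _ in range(3)]}
            for _ in range(N_LEVELS - 1)
        ]
        # final level at N: reduce block, sigmoid-activated block, 1x1 conv
        self.final_reduce = Block(2 * c, c, rng, dtype=dtype)
        self.final_block = Block(c, c, rng, activation="sigmoid", dtype=dtype)
        self.conv_out = nn.Conv2d(c, 1, 1, rng, dtype=dtype)
        self.out_act = nn.Sigmoid()

    # -- introspection ------------------------------------------------------

    def traverse(self):
        """Yield (path, kind, side) for every layer in execution order.

        ``kind`` is one of conv/bn/activation/pool/unpool; pooling and
        unpooling are stateless in this engine, so they appear as markers at
        their position in the graph.
        """
        yield "encoder.conv_in", "conv", "encoder"
        for lvl, blocks in enumerate(self.enc_blocks):
            if lvl > 0:
                yield f"encoder.pool{lvl}", "pool", "encoder"
            for i, blk in enumerate(blocks):
                for layer in blk.layers:
                    yield f"encoder.level{lvl}.block{i}.{layer.kind}", layer.kind, "encoder"
        yield "encoder.pool5", "pool", "encoder"
        for i, lvl in enumerate(self.dec_levels):
            yield f"decoder.level{i}.unpool", "unpool", "decoder"
            for layer in lvl["reduce"].layers:
                yield f"decoder.level{i}.reduce.{layer.kind}", layer.kind, "decoder"
            for j, blk in enumerate(lvl["blocks"]):
                for layer in blk.layers:
                    yield f"decoder.level{i}.block{j}.{layer.kind}", layer.kind, "decoder"
        yield "decoder.final.unpool", "unpool", "decoder"
        for layer in self.final_reduce.layers:
            yield f"decoder.final.reduce.{layer.kind}", layer.kind, "decoder"
        for layer in self.final_block.layers:
            yield f"decoder.final.block.{layer.kind}", layer.kind, "decoder"
        yield "decoder.final.conv_out", "conv", "decoder"
        yield "decoder.final.out_activation", "activation", "decoder"

    def spec(self) -> NetworkSpec:
        """Layer inventory computed by traversing the instantiated graph."""
        counts = {"conv": 0, "pool": 0, "unpool": 0, "bn": 0, "activation": 0}
        enc_conv = dec_conv = 0
        for _, kind, side in self.traverse():
            counts[kind] += 1
            if kind == "conv":
                if side == "encoder":
                    enc_conv += 1
                else:
                    dec_conv += 1
        return NetworkSpec(
            input_size=self.input_size, base_channels=self.base_channels,
            conv_count=counts["conv"], pool_count=counts["pool"],
            unpool_count=counts["unpool"], encoder_conv_count=enc_conv,
            decoder_conv_count=dec_conv, bn_count=counts["bn"],
            activation_count=counts["activation"],
        )

    def _param_layers(self) -> list[tuple[str, nn.Layer]]:
        out: list[tuple[str, nn.Layer]] = [("encoder.conv_in", self.conv_in)]
        for lvl, blocks in enumerate(self.enc_blocks):
            for i, blk in enumerate(blocks):
                out += [(f"encoder.level{lvl}.block{i}.bn", blk.bn),
                        (f"encoder.level{lvl}.block{i}.conv", blk.conv)]
        for i, lvl in enumerate(self.dec_levels):
            out += [(f"decoder.level{i}.reduce.bn", lvl["reduce"].bn),
                    (f"decoder.level{i}.reduce.conv", lvl["reduce"].conv)]
            for j, blk in enumerate(lvl["blocks"]):
                out += [(f"decoder.level{i}.block{j}.bn", blk.bn),
                        (f"decoder.level{i}.block{j}.conv", blk.conv)]
        out += [("decoder.final.reduce.bn", self.final_reduce.bn),
                ("decoder.final.reduce.conv", self.final_reduce.conv),
                ("decoder.final.block.bn", self.final_block.bn),
                ("decoder.final.block.conv", self.final_block.conv),
                ("decoder.final.conv_out", self.conv_out)]
        return out

    def named_parameters(self):
        """Yield (key, param, grad) for the optimizer; stable ordering."""
        for name, layer in self._param_layers():
            for pname, arr in layer.params.items():
                yield f"{name}.{pname}", arr, layer.grads.get(pname)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Run a (B, 1, N, N) batch to a (B, 1, N, N) probability map."""
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2] != self.input_size \
                or x.shape[3] != self.input_size:
            raise ValueError(f"expected (B, 1, {self.input_size}, {self.input_size}), "
                             f"got {x.shape}")
        x = x.astype(self.dtype, copy=False)

        t = self.conv_in.forward(x, training)
        u = t
        for blk in self.enc_blocks[0]:
            u = blk.forward(u, training)
        acts = [t + u]  # encoder addition outputs, one per level
        pool_idx: list[np.ndarray] = []
        prev = acts[0]
        for lvl in range(1, N_LEVELS):
            p, idx = nn.max_pool2x2(prev)
            pool_idx.append(idx)
            u = p
            for blk in self.enc_blocks[lvl]:
                u = blk.forward(u, training)
            prev = p + u
            acts.append(prev)
        p5, idx5 = nn.max_pool2x2(prev)
        pool_idx.append(idx5)

        d = p5
        for i, lvl in enumerate(self.dec_levels):
            up = nn.max_unpool2x2(d, pool_idx[N_LEVELS - 1 - i])
            cat = np.concatenate([up, acts[N_LEVELS - 1 - i]], axis=1)
            r = lvl["reduce"].forward(cat, training)
            v = r
            for blk in lvl["blocks"]:
                v = blk.forward(v, training)
            d = r + v
        up = nn.max_unpool2x2(d, pool_idx[0])
        cat = np.concatenate([up, acts[0]], axis=1)
        r = self.final_reduce.forward(cat, training)
        s = self.final_block.forward(r, training)
        z = self.conv_out.forward(s, training)
        prob = self.out_act.forward(z, training)
        if training:
            self._pool_idx = pool_idx
        return prob

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate a probability-map gradient; fills every layer's grads."""
        pool_idx = self._pool_idx
        c = self.base_channels

        dz = self.out_act.backward(dprob)
        ds = self.conv_out.backward(dz)
        dr = self.final_block.backward(ds)
        dcat = self.final_reduce.backward(dr)
        dup, d_enc0 = dcat[:, :c], dcat[:, c:]
        d_enc = [None] * N_LEVELS  # gradients flowing into encoder additions
        d_enc[0] = d_enc0
        dd = nn.max_unpool2x2_backward(dup, pool_idx[0])

        for i in reversed(range(len(self.dec_levels))):
            lvl = self.dec_levels[i]
            dv = dd
            for blk in reversed(lvl["blocks"]):
                dv = blk.backward(dv)
            dr = dd + dv  # residual addition: d = r + blocks(r)
            dcat = lvl["reduce"].backward(dr)
            dup, de = dcat[:, :c], dcat[:, c:]
            enc_level = N_LEVELS - 1 - i
            d_enc[enc_level] = de
            dd = nn.max_unpool2x2_backward(dup, pool_idx[enc_level])

        # dd is now the gradient at pool 5's output
        da = nn.max_pool2x2_backward(dd, pool_idx[N_LEVELS - 1]) + d_enc[N_LEVELS - 1]
        for lvl in reversed(range(1, N_LEVELS)):
            du = da
            for blk in reversed(self.enc_blocks[lvl]):
                du = blk.backward(du)
            dp = da + du  # a = p + blocks(p)
            da = nn.max_pool2x2_backward(dp, pool_idx[lvl - 1])
            if lvl - 1 > 0:
                da = da + d_enc[lvl - 1]
        da = da + d_enc[0]
        du = da
        for blk in reversed(self.enc_blocks[0]):
            du = blk.backward(du)
        dt = da + du  # a0 = t + blocks(t)
        self.conv_in.backward(dt)
        self._pool_idx = None

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save weights (npz) plus a JSON sidecar with the layer inventory."""
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for name, layer in self._param_layers():
            for pname, arr in layer.params.items():
                arrays[f"{name}.{pname}"] = arr
            if isinstance(layer, nn.BatchNorm2d):
                arrays[f"{name}.running_mean"] = layer.running_mean
                arrays[f"{name}.running_var"] = layer.running_var
        np.savez(path, **arrays)
        sidecar = {"input_size": self.input_size, "base_channels": self.base_channels,
                   "spec": asdict(self.spec())}
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "RUNet":
        path = Path(path)
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            sidecar = json.load(fh)
        model = cls(sidecar["input_size"], sidecar["base_channels"])
        with np.load(path) as data:
            for name, layer in model._param_layers():
                for pname in layer.params:
                    layer.params[pname][...] = data[f"{name}.{pname}"]
                if isinstance(layer, nn.BatchNorm2d):
                    layer.running_mean[...] = data[f"{name}.running_mean"]
                    layer.running_var[...] = data[f"{name}.running_var"]
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self._param_layers():
            for pname, arr in layer.params.items():
                out[f"{name}.{pname}"] = arr.copy()
            if isinstance(layer, nn.BatchNorm2d):
                out[f"{name}.running_mean"] = layer.running_mean.copy()
                out[f"{name}.running_var"] = layer.running_var.copy()
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self._param_layers():
            for pname in layer.params:
                layer.params[pname][...] = state[f"{name}.{pname}"]
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean[...] = state[f"{name}.running_mean"]
                layer.running_var[...] = state[f"{name}.running_var"]


def build_runet(input_size: int, base_channels: int = 64,
                seed: int = 0) -> tuple[NetworkSpec, RUNet]:
    """Instantiate the network and return its traversal-derived inventory."""
    model = RUNet(input_size, base_channels, seed=seed)
    return model.spec(), model


def keep_largest_component(mask: np.ndarray) -> np.ndarray:
    """Retain only the largest 3-D connected component of a binary array."""
    labeled, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return (labeled == keep).astype(mask.dtype)


def predict_volume(model: RUNet, volume: MRVolume, threshold: float = 0.5,
                   batch_size: int = 8, largest_component: bool = False) -> SegmentationResult:
    """Slice-wise inference on a z-scored volume; mask = probability >= threshold."""
    if volume.n != model.input_size:
        raise ValueError(f"volume in-plane size {volume.n} != model input size "
                         f"{model.input_size}")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    slices = volume.voxels[:, None].astype(model.dtype)  # (S,1,N,N)
    probs = []
    for start in range(0, len(slices), batch_size):
        probs.append(model.forward(slices[start:start + batch_size], training=False))
    probability = np.concatenate(probs, axis=0)[:, 0]
    mask_arr = (probability >= threshold).astype(np.uint8)
    if largest_component:
        mask_arr = keep_largest_component(mask_arr)
    mask = BinaryMask(voxels=mask_arr, spacing_mm=volume.spacing_mm,
                      subject_id=volume.subject_id)
    return SegmentationResult(probability=probability, mask=mask, threshold=threshold)
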
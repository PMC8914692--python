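"""Feature-extraction backbones.

Every backbone maps a ``(1, 1, H, W)`` luminance image to a stride-16
feature map of spatial size ``(ceil(H/16), ceil(W/16))``.  Two backbones
are registered:

``tiny_test``
    A four-stage conv/pool stack small enough to train on a CPU in
    minutes; used for desk-scale experiments and the test suite.

``paper_resnet50``
    A randomly initialized network with the ResNet-50 bottleneck stage
    layout (stages 1-4, i.e. up to the 1024-channel stage feeding the
    proposal network).  Downsampling uses ceil-mode max pooling instead
    of strided convolution and there is no batch normalization; it
    honors the stride/shape contract for full-scale inputs but ships
    without pretrained weights.
"""

from __future__ import annotations

import numpy as np

from .nn import Bottleneck, Conv2d, MaxPool2x2, Module, ReLU, Sequential

STRIDE = 16


class TinyBackbone(Sequential):
    def __init__(self, rng: np.random.Generator,
                 channels: tuple[int, ...] = (8, 16, 32, 48)):
        mods = []
        cin = 1
        for c in channels:
            mods += [Conv2d(cin, c, 3, rng), ReLU(), MaxPool2x2()]
            cin = c
        super().__init__(*mods)
        self.out_channels = channels[-1]


class ResNet50Layout(Sequential):
    def __init__(self, rng: np.random.Generator):
        mods: list[Module] = [Conv2d(1, 64, 7, rng, pad=3), ReLU(),
                              MaxPool2x2(), MaxPool2x2()]
        cin = 64
        for n_blocks, mid, out in ((3, 64, 256), (4, 128, 512),
                                   (6, 256, 1024)):
            if out != 256:  # stages 3 and 4 halve resolution first
                mods.append(MaxPool2x2())
            for _ in range(n_blocks):
                mods.append(Bottleneck(cin, mid, out, rng))
                cin = out
        super().__init__(*mods)
        self.out_channels = 1024


_REGISTRY = {
    "tiny_test": TinyBackbone,
    "paper_resnet50": ResNet50Layout,
}


def get_backbone(name: str, rng: np.random.Generator) -> Sequential:
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown backbone {name!r}; choose from {sorted(_REGISTRY)}")
    return cls(rng)
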
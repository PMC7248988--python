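"""Deconvolution-based introspection: project kernel activations to input space.

To see what a trained kernel responds to, its activation map is isolated
(all other maps in that layer zeroed) and pushed back through the network:
for each block, average pooling is reversed by uniform redistribution (the
adjoint of mean pooling — the max-pooling "switches" of the classic deconvnet
have no analogue here), ReLU is re-applied, and the layer's own kernels are
applied transposed (flipped).  Biases are omitted on the reverse pass, the
standard deconvnet convention.  The result lives in input coordinates
(channels x 768), so per-channel norms quantify which sensor channels drive
the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .cnn import FatigueCNN
from .nn import avg_unpool, conv1d_adjoint_input, relu

__all__ = ["Projection", "top_kernel", "project_activation", "channel_attribution"]


@dataclass
class Projection:
    """A kernel activation mapped back to input coordinates."""

    values: np.ndarray  # (channels, input_length)
    source_layer: int  # 1-based block index
    source_kernel: int
    activation_norm: float

    def channel_norms(self) -> np.ndarray:
        """Per-channel L2 norms — the channel-relevance measurement."""
        return np.linalg.norm(self.values, axis=1)


def _check_layer(model: FatigueCNN, layer: int) -> None:
    if not 1 <= layer <= model.spec.n_layers:
        raise ValueError(
            f"layer must be in 1..{model.spec.n_layers}, got {layer}"
        )


def top_kernel(model: FatigueCNN, segment_matrix: np.ndarray, layer: int) -> int:
    """Index of the kernel with the largest-L2 activation map at ``layer``.

    Activation maps are the block outputs (post-ReLU, post-pool).  Ties —
    including the all-zero input — resolve to the lowest index.
    """
    _check_layer(model, layer)
    cache = model.forward_cached(np.asarray(segment_matrix)[None])
    maps = cache["pool"][layer - 1][0]  # (filters, L)
    norms = np.linalg.norm(maps, axis=1)
    return int(np.argmax(norms))


def project_activation(
    model: FatigueCNN, segment_matrix: np.ndarray, layer: int, kernel: int,
    activation_scale: float = 1.0,
) -> Projection:
    """Project one kernel's activation at ``layer`` back to the input domain.

    ``activation_scale`` multiplies the retained activation map before the
    reverse pass (a sensitivity handle; every reverse operation is positively
    homogeneous, so scaling the activation by c > 0 scales the projection by c).
    """
    _check_layer(model, layer)
    spec = model.spec
    if not 0 <= kernel < spec.conv_filters[layer - 1]:
        raise ValueError(
            f"kernel must be in 0..{spec.conv_filters[layer - 1] - 1}, got {kernel}"
        )
    x = np.asarray(segment_matrix, dtype=np.float64)
    cache = model.forward_cached(x[None])

    a = cache["pool"][layer - 1][0].copy()  # (filters, L_pool)
    keep = a[kernel].copy() * float(activation_scale)
    a[:] = 0.0
    a[kernel] = keep
    act_norm = float(np.linalg.norm(keep))

    h = a
    for l in range(layer, 0, -1):
        conv_len = cache["conv"][l - 1].shape[-1]
        h = avg_unpool(h, conv_len, spec.pool_kernel)
        h = relu(h)
        h = conv1d_adjoint_input(h, model.params[f"W{l - 1}"])
    assert h.shape == spec.input_shape
    return Projection(
        values=h, source_layer=layer, source_kernel=kernel, activation_norm=act_norm
    )


def channel_attribution(
    model: FatigueCNN, segment_matrix: np.ndarray, layer: int
) -> Dict[str, object]:
    """Project the top kernel of ``layer`` and report per-channel L2 norms."""
    k = top_kernel(model, segment_matrix, layer)
    proj = project_activation(model, segment_matrix, layer, k)
    return {
        "layer": layer,
        "kernel": k,
        "activation_norm": proj.activation_norm,
        "channel_norms": proj.channel_norms(),
        "projection": proj,
    }
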
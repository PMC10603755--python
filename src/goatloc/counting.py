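"""Closed-form parameter and multiply-accumulate (MAC) accounting.

Layer descriptors are plain dataclasses so that model complexity can be
computed without instantiating weights.  Conventions: one MAC is one
multiply-accumulate (not two FLOPs); biases and normalization layers
contribute parameters but no MACs, matching how detector complexity
tables are usually reported.
"""

from __future__ import annotations

from dataclasses import dataclass


class UnsupportedLayerError(ValueError):
    pass


@dataclass(frozen=True)
class LayerSpec:
    """One countable layer.

    kind: "conv" (k x k, stride, optional bias), "linear", or "norm"
    (per-channel scale+shift).  ``applied_per_pixel`` distinguishes linear
    layers applied once per image (e.g. SE bottlenecks on pooled vectors)
    from dense heads; it only affects MACs, not parameters.
    """

    kind: str
    cin: int = 0
    cout: int = 0
    kernel: int = 1
    stride: int = 1
    bias: bool = True
    channels: int = 0  # for norm layers

    def n_params(self) -> int:
        if self.kind == "conv":
            return self.kernel * self.kernel * self.cin * self.cout + (
                self.cout if self.bias else 0
            )
        if self.kind == "linear":
            return self.cin * self.cout + (self.cout if self.bias else 0)
        if self.kind == "norm":
            return 2 * self.channels
        raise UnsupportedLayerError(f"unknown layer kind {self.kind!r}")


def count_parameters(layer_specs) -> int:
    """Total trainable parameters of a stack of layer descriptors."""
    return sum(spec.n_params() for spec in layer_specs)


def count_macs(layer_specs, input_shape) -> int:
    """Total MACs for one forward pass at the given (H, W) input size.

    Spatial dimensions are propagated through conv strides assuming
    'same' padding (output = ceil(in / stride)); linear layers count
    cin * cout once.  Norm layers are free.
    """
    h, w = input_shape
    total = 0
    for spec in layer_specs:
        if spec.kind == "conv":
            h = -(-h // spec.stride)
            w = -(-w // spec.stride)
            total += spec.kernel * spec.kernel * spec.cin * spec.cout * h * w
        elif spec.kind == "linear":
            total += spec.cin * spec.cout
        elif spec.kind == "norm":
            pass
        else:
            raise UnsupportedLayerError(f"unknown layer kind {spec.kind!r}")
    return total
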
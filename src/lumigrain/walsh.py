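"""Walsh codewords from the Hadamard recursion, and the label codec.

The order-2N matrix is built from the order-N matrix by tiling it three times
and logically complementing the lower-right block, starting from the 1x1
matrix [0].  Rows of the order-8 matrix serve as class codewords: any two
distinct rows differ in exactly half their positions, so the 5-class codebook
has minimum Hamming distance 4 and corrects any single bit error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["hadamard", "Codebook", "encode", "decode"]


def hadamard(order: int) -> np.ndarray:
    """Binary {0,1} Hadamard-derived Walsh matrix of a power-of-two order."""
    if order < 1 or order & (order - 1):
        raise ValueError("order must be a positive power of two")
    h = np.zeros((1, 1), dtype=np.int8)
    while h.shape[0] < order:
        h = np.block([[h, h], [h, 1 - h]])
    return h


@dataclass(frozen=True)
class Codebook:
    """The first ``num_classes`` rows of the order-``order`` Walsh matrix."""

    num_classes: int
    order: int

    def __post_init__(self) -> None:
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.num_classes > self.order:
            raise ValueError("num_classes cannot exceed the matrix order")
        hadamard(self.order)  # validates power-of-two order

    @property
    def codewords(self) -> np.ndarray:
        return hadamard(self.order)[: self.num_classes]

    def to_dict(self) -> dict:
        return {
            "num_classes": self.num_classes,
            "order": self.order,
            "codewords": self.codewords.tolist(),
        }


def encode(class_index: int, codebook: Codebook) -> np.ndarray:
    """Codeword row for a 0-based class index."""
    if not 0 <= class_index < codebook.num_classes:
        raise ValueError(f"class index {class_index} out of range")
    return codebook.codewords[class_index].copy()


def decode(soft_outputs: np.ndarray, codebook: Codebook,
           method: str = "euclidean") -> tuple[int, float]:
    """Nearest-codeword decoding of per-bit soft outputs in [0, 1].

    ``euclidean`` minimizes the squared distance to each codeword (soft
    decision); ``hamming`` thresholds at 0.5 first.  Ties break toward the
    lowest class index, so decoding is a pure function.
    """
    y = np.asarray(soft_outputs, dtype=float)
    if y.shape != (codebook.order,):
        raise ValueError(f"expected {codebook.order} soft outputs, got shape {y.shape}")
    cw = codebook.codewords.astype(float)
    if method == "euclidean":
        dists = np.sum((cw - y) ** 2, axis=1)
    elif method == "hamming":
        bits = (y >= 0.5).astype(float)
        dists = np.sum(cw != bits, axis=1).astype(float)
    else:
        raise ValueError("method must be 'euclidean' or 'hamming'")
    idx = int(np.argmin(dists))  # argmin takes the first minimum: lowest index
    return idx, float(dists[idx])
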
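"""Minimal neural-network toolkit used by the vascular graph classifier.

A small reverse-mode automatic-differentiation engine over numpy arrays
(:mod:`vgn.nn.autodiff`), dense message-passing layers for complete
weighted graphs (:mod:`vgn.nn.layers`), and the Adam optimizer with a
multistep learning-rate schedule (:mod:`vgn.nn.optim`).
"""

def _tune_allocator() -> None:
    """Keep freed numpy buffers in the process heap.

    Training repeatedly allocates and frees identical mid-sized arrays;
    with glibc's default trim/mmap thresholds those pages bounce back to
    the kernel on every step, and re-faulting them dominates wall time.
    Raising both thresholds lets the allocator recycle warm pages.
    """
    import ctypes

    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-1, ctypes.c_int(1 << 30))  # M_TRIM_THRESHOLD
        libc.mallopt(-3, ctypes.c_int(1 << 30))  # M_MMAP_THRESHOLD
    except (OSError, AttributeError):  # non-glibc platforms
        pass


_tune_allocator()

from .autodiff import Tensor
from .layers import GATLayer, GINLayer, Linear, VGNNetwork
from .optim import Adam, MultiStepLR

__all__ = [
    "Tensor",
    "Linear",
    "GINLayer",
    "GATLayer",
    "VGNNetwork",
    "Adam",
    "MultiStepLR",
]
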
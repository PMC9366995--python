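"""Independent brute-force reference for the single-model compressor.

This accumulator is deliberately written along a different path from the
implementation: contexts are plain strings, counts live in nested dicts, and
the probability product is accumulated symbol by symbol. It serves as the
oracle for code-length equivalence checks and must stay independent of
nucomp.fcm.
"""

import math


def single_model_bits(seq: str, k: int = 1, alpha: float = 1.0) -> float:
    """Ideal code length of ``seq`` under one order-k model, no IR detection.

    Context starts as k A's (matching the all-A initialization convention)
    and counts start empty, so the first symbol costs exactly 2 bits.
    """
    counts: dict[str, dict[str, int]] = {}
    history = "A" * k
    total = 0.0
    for ch in seq:
        ctx = history[-k:] if k else ""
        ctx_counts = counts.setdefault(ctx, {})
        seen = sum(ctx_counts.values())
        p = (ctx_counts.get(ch, 0) + alpha) / (seen + 4.0 * alpha)
        total += -math.log2(p)
        ctx_counts[ch] = ctx_counts.get(ch, 0) + 1
        history = history + ch
    return total
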
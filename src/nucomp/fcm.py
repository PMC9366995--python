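"""Adaptive finite-context-model compressor with inverted-repeat detection.

The compressor is a mixture of order-k finite-context models (FCMs). Each
model predicts the next base from smoothed counts of (context, symbol)
occurrences,

    P(s | ctx) = (n(ctx, s) + alpha) / (sum_s' n(ctx, s') + 4 * alpha),

and the mixture combines model predictions with performance-derived weights:
after each symbol, w_m <- w_m^gamma_m * P_m(observed), renormalized. gamma
close to 1 gives long memory of past performance; gamma = 0 forgets history
entirely. The output is the ideal code length, sum_i -log2(p_mix(x_i)) bits;
no bitstream is produced (an arithmetic coder would add only O(1) bits).

Inverted-repeat (IR) detection is an update-rule variant: besides (or instead
of) counting the forward (context, symbol) pair, a model counts the
reverse-complemented reading of the same (k+1)-mer window. Predictions always
look up the forward context, so a region whose reverse complement appeared
earlier scores the counts that the earlier text seeded. The three modes are

* ir_mode 0 - forward counts only,
* ir_mode 1 - forward and reverse-complement counts in the same table,
* ir_mode 2 - reverse-complement counts only.

Base encoding: A=0, C=1, G=2, T=3; complement(b) = 3 - b. Context registers
start at the all-A context and count tables start empty, so the first symbol
of any sequence costs exactly 2 bits under a fresh single model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = "ACGT"

MAX_ORDER = 16  # memory guard: 4^k contexts
MAX_GAMMA = 0.99


@dataclass(frozen=True)
class ModelSpec:
    """One finite-context model: order, smoothing, mixing decay, IR mode."""

    order_k: int
    alpha: float = 1.0
    gamma: float = 0.9
    ir_mode: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.order_k <= MAX_ORDER:
            raise ValueError(f"order_k must be in [0, {MAX_ORDER}], got {self.order_k}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not 0.0 <= self.gamma <= MAX_GAMMA:
            raise ValueError(f"gamma must be in [0, {MAX_GAMMA}], got {self.gamma}")
        if self.ir_mode not in (0, 1, 2):
            raise ValueError(f"ir_mode must be 0, 1 or 2, got {self.ir_mode}")


@dataclass(frozen=True)
class CompressorConfig:
    """An ordered mixture of models, with an optional global IR override.

    ``ir_override`` forces the IR mode of every model when not None; it is
    how the IR0/IR1/IR2 measurement variants of a level are produced.
    """

    models: tuple[ModelSpec, ...]
    ir_override: int | None = None
    label: str = "custom"

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("config needs at least one model")
        object.__setattr__(self, "models", tuple(self.models))
        if self.ir_override not in (None, 0, 1, 2):
            raise ValueError(f"ir_override must be None, 0, 1 or 2, got {self.ir_override}")

    def effective_models(self) -> tuple[ModelSpec, ...]:
        """Models with ``ir_override`` applied (if set)."""
        if self.ir_override is None:
            return self.models
        return tuple(replace(m, ir_mode=self.ir_override) for m in self.models)

    def with_ir_override(self, ir_override: int | None) -> "CompressorConfig":
        suffix = "" if ir_override is None else f"-ir{ir_override}"
        return replace(self, ir_override=ir_override, label=self.label + suffix)


def level16() -> CompressorConfig:
    """The default two-model mixture used throughout the package.

    Model 1: order 1, alpha 1, gamma 0.7, no IR detection.
    Model 2: order 12, alpha 1/50, gamma 0.97, IR detection alongside the
    regular context model. A short-memory low-order model plus a deeper
    IR-aware model suits small, compact genomes where repeats and inverted
    repeats are separated by little sequence.
    """
    return CompressorConfig(
        models=(
            ModelSpec(order_k=1, alpha=1.0, gamma=0.7, ir_mode=0),
            ModelSpec(order_k=12, alpha=1.0 / 50.0, gamma=0.97, ir_mode=1),
        ),
        label="level16",
    )


def _builtin_levels() -> dict[str, CompressorConfig]:
    return {
        "level16": level16(),
        # lightweight single-model alternatives, mainly for level sweeps
        "order4": CompressorConfig((ModelSpec(4, 1.0, 0.9, 0),), label="order4"),
        "order8": CompressorConfig((ModelSpec(8, 0.1, 0.95, 0),), label="order8"),
    }


def get_level(name: str) -> CompressorConfig:
    levels = _builtin_levels()
    if name not in levels:
        raise KeyError(f"unknown level {name!r}; built-ins: {sorted(levels)}")
    return levels[name]


def load_levels(path: str | Path) -> dict[str, CompressorConfig]:
    """Load level definitions from a JSON file.

    Format: {"label": {"models": [{"order_k": .., "alpha": .., "gamma": ..,
    "ir_mode": ..}, ...]}, ...}
    """
    with open(path) as handle:
        raw = json.load(handle)
    levels = {}
    for label, spec in raw.items():
        models = tuple(ModelSpec(**m) for m in spec["models"])
        levels[label] = CompressorConfig(models=models, label=label)
    return levels


@dataclass
class CountTable:
    """Sparse (context, symbol) occurrence counts for one model.

    ``counts`` maps a context integer in [0, 4^k) to a 5-slot list:
    per-symbol counts in slots 0-3 and their running total in slot 4.
    """

    order_k: int
    counts: dict = field(default_factory=dict)

    def get(self, context: int) -> list | None:
        return self.counts.get(context)

    def increment(self, context: int, symbol: int) -> None:
        cnt = self.counts.get(context)
        if cnt is None:
            self.counts[context] = cnt = [0, 0, 0, 0, 0]
        cnt[symbol] += 1
        cnt[4] += 1


@dataclass
class MixerState:
    """Normalized per-model mixture weights."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixer weights must sum to 1")


@dataclass
class CompressionResult:
    """Ideal code length of one sequence under one configuration."""

    total_bits: float
    per_symbol_bits: np.ndarray
    config_label: str

    @property
    def length(self) -> int:
        return len(self.per_symbol_bits)

    @property
    def nc(self) -> float:
        """Normalized compression: total bits over the 2*|x| bit capacity."""
        return self.total_bits / (2.0 * self.length)


def symbol_distribution(table: CountTable, context: int, alpha: float) -> np.ndarray:
    """Smoothed next-symbol distribution for one context.

    P(s) = (n(ctx, s) + alpha) / (total(ctx) + 4 * alpha). An unseen context
    yields the uniform distribution.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    cnt = table.get(context)
    if cnt is None:
        return np.full(4, 0.25)
    denom = cnt[4] + 4.0 * alpha
    return np.array([(cnt[s] + alpha) / denom for s in range(4)])


def ir_expand(window: Sequence[int]) -> tuple[int, int]:
    """Reverse-complement reading of a (k+1)-mer window.

    ``window`` is (x_{i-k}, ..., x_{i-1}, x_i) as base indices. The IR word is
    the reverse complement (comp(x_i), ..., comp(x_{i-k})); its first k
    symbols, encoded as an integer (oldest symbol in the highest bits), form
    the IR context and its last symbol comp(x_{i-k}) is the IR symbol.
    Applying ir_expand to the reverse complement of a window recovers the
    original window's forward (context, symbol) pair.
    """
    if len(window) < 1:
        raise ValueError("window must hold at least one symbol")
    ir_word = [3 - b for b in reversed(window)]
    ctx = 0
    for b in ir_word[:-1]:
        ctx = (ctx << 2) | b
    return ctx, ir_word[-1]


def update_model(table: CountTable, window: Sequence[int], ir_mode: int) -> CountTable:
    """Record one (k+1)-mer observation under the given IR mode (in place)."""
    ctx = 0
    for b in window[:-1]:
        ctx = (ctx << 2) | b
    if ir_mode in (0, 1):
        table.increment(ctx, window[-1])
    if ir_mode in (1, 2):
        ir_ctx, ir_sym = ir_expand(window)
        table.increment(ir_ctx, ir_sym)
    return table


def mix_step(
    predictions: Sequence[np.ndarray],
    state: MixerState,
    gammas: Sequence[float],
    observed: int,
) -> tuple[np.ndarray, MixerState]:
    """One mixture step: blend predictions, then reweight on the outcome.

    The mixed distribution uses the weights *before* the symbol is observed;
    afterwards each weight decays toward its model's realized probability:
    w_m <- w_m^gamma_m * P_m(observed), renormalized.
    """
    w = state.weights
    p_mix = np.zeros(4)
    for wm, pm in zip(w, predictions):
        p_mix += wm * pm
    new_w = np.array(
        [wm**g * pm[observed] for wm, g, pm in zip(w, gammas, predictions)]
    )
    total = new_w.sum()
    if total <= 0.0:
        raise ZeroDivisionError("all mixer weights vanished; alpha must be positive")
    return p_mix, MixerState(new_w / total)


def encode_sequence(seq: str) -> list[int]:
    """Map residues to base indices; non-ACGT symbols are an error."""
    try:
        return [BASE_INDEX[c] for c in seq]
    except KeyError as exc:
        raise ValueError(
            f"symbol {exc.args[0]!r} is outside the A/C/G/T alphabet; "
            "sanitize the sequence first (io_seq.sanitize_sequence)"
        ) from None


def compress_sequence(seq: str, config: CompressorConfig) -> CompressionResult:
    """Ideal code length of ``seq`` under a model mixture.

    Symbols are processed left to right. Every model emits its smoothed
    next-symbol probability from its forward context register (initialized to
    the all-A context over an empty table), the mixture probability prices the
    observed symbol at -log2 p, the mixer reweights, and every model then
    records the (k+1)-mer window according to its effective IR mode.
    Deterministic: identical (seq, config) gives bit-identical results.
    """
    syms = encode_sequence(seq)
    n = len(syms)
    if n == 0:
        raise ValueError("cannot compress an empty sequence")

    specs = config.effective_models()
    nm = len(specs)
    alphas = [m.alpha for m in specs]
    alpha4 = [4.0 * m.alpha for m in specs]
    gammas = [m.gamma for m in specs]
    irms = [m.ir_mode for m in specs]
    masks = [(1 << (2 * m.order_k)) - 1 for m in specs]
    rcshifts = [2 * m.order_k for m in specs]
    tables = [{} for _ in specs]
    ctxs = [0] * nm  # all-A forward context
    rcs = [(1 << (2 * (m.order_k + 1))) - 1 for m in specs]  # all-T rc register
    weights = [1.0 / nm] * nm
    probs = [0.0] * nm
    bits = np.empty(n)
    log2 = math.log2
    mrange = range(nm)

    for i in range(n):
        s = syms[i]
        p_mix = 0.0
        for m in mrange:
            cnt = tables[m].get(ctxs[m])
            if cnt is None:
                p = 0.25
            else:
                p = (cnt[s] + alphas[m]) / (cnt[4] + alpha4[m])
            probs[m] = p
            p_mix += weights[m] * p
        bits[i] = -log2(p_mix)
        total = 0.0
        for m in mrange:
            wm = weights[m] ** gammas[m] * probs[m]
            weights[m] = wm
            total += wm
        for m in mrange:
            weights[m] /= total
        comp_s = 3 - s
        for m in mrange:
            table = tables[m]
            irm = irms[m]
            ctx = ctxs[m]
            if irm != 2:
                cnt = table.get(ctx)
                if cnt is None:
                    table[ctx] = cnt = [0, 0, 0, 0, 0]
                cnt[s] += 1
                cnt[4] += 1
            rc = (rcs[m] >> 2) | (comp_s << rcshifts[m])
            rcs[m] = rc
            if irm != 0:
                ir_ctx = rc >> 2
                cnt = table.get(ir_ctx)
                if cnt is None:
                    table[ir_ctx] = cnt = [0, 0, 0, 0, 0]
                cnt[rc & 3] += 1
                cnt[4] += 1
            ctxs[m] = ((ctx << 2) | s) & masks[m]

    return CompressionResult(
        total_bits=float(bits.sum()),
        per_symbol_bits=bits,
        config_label=config.label,
    )


@dataclass
class SweepSummary:
    """Per-record winners and per-config summary of a level sweep."""

    best_label: dict  # accession -> winning config label
    best_frequency: dict  # config label -> fraction of records won
    nc_sum: dict  # config label -> sum of NC over records


def best_level_sweep(records: Iterable, configs: Sequence[CompressorConfig]) -> SweepSummary:
    """Compare configurations across records by NC.

    For each record the config with the lowest NC wins (ties go to the lowest
    config index, so the result is order-stable); per config, reports the
    fraction of records won and the sum of NC over all records.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("need at least one config")
    labels = [c.label for c in configs]
    if len(set(labels)) != len(labels):
        raise ValueError("config labels must be unique")
    best_label: dict = {}
    wins = {lab: 0 for lab in labels}
    nc_sum = {lab: 0.0 for lab in labels}
    n_records = 0
    for rec in records:
        n_records += 1
        ncs = [compress_sequence(rec.residues, cfg).nc for cfg in configs]
        for lab, nc in zip(labels, ncs):
            nc_sum[lab] += nc
        winner = labels[int(np.argmin(ncs))]  # argmin takes the first minimum
        best_label[rec.accession] = winner
        wins[winner] += 1
    if n_records == 0:
        raise ValueError("need at least one record")
    freq = {lab: wins[lab] / n_records for lab in labels}
    return SweepSummary(best_label=best_label, best_frequency=freq, nc_sum=nc_sum)
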
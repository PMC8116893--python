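"""Feature-distribution histogram alignment: the core loss of the package.

During transductive adaptation a source batch and a target batch are both
forwarded through the network and activations are tapped at selected layers.
For each tapped layer i the source activations ``A_i`` are histogram-matched
to the target activations ``B_i`` via a monotone CDF/quantile mapping
``H(A_i, B_i)``, and the histogram loss is

    L_hist = sum_i LogCosh(A_i, H(A_i, B_i))

with the matched matrices treated as stored constants (stop-gradient): the
gradient flows only through ``A_i``, pushing the network to produce
source-domain features whose value distribution matches the target domain.
The joint objective is ``L_total = L_ce + lambda * L_hist``, where the
cross-entropy term uses source labels only.

Matching pools all elements of a layer's batch activation tensor into a single
value multiset (a per-channel mode is available), so the loss compares
distributions rather than per-sample values and needs a batch (default 32)
to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, logcosh_to_const, scalar_sum

__all__ = ["HistAlignConfig", "LossBreakdown", "match_histograms", "logcosh",
           "histogram_loss", "total_loss"]


@dataclass(frozen=True)
class HistAlignConfig:
    """Weight, batch size and histogram resolution for the alignment loss.

    ``lambda_weight`` defaults to 1.0 (the method is insensitive within
    roughly 1±0.6; much larger overshoots, much smaller has no effect).
    ``match_batch`` is the number of samples pooled per histogram (32).
    ``bins`` is the number of quantile knots of the CDF mapping.
    """

    lambda_weight: float = 1.0
    match_batch: int = 32
    bins: int = 256
    pooling: str = "per_layer_pooled"  # or "per_channel"

    def __post_init__(self) -> None:
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be non-negative")
        if self.bins < 2:
            raise ValueError("need at least 2 histogram bins")
        if self.match_batch < 2:
            raise ValueError("histogram matching needs a batch of at least 2")
        if self.pooling not in ("per_layer_pooled", "per_channel"):
            raise ValueError(f"unknown pooling mode {self.pooling!r}")


@dataclass
class LossBreakdown:
    """One optimisation step's loss terms: L_total = L_ce + lambda * L_hist."""

    ce: float
    hist: float
    lambda_weight: float
    total: float
    per_layer_hist: dict[str, float] = field(default_factory=dict)


def match_histograms(source_values: np.ndarray, target_values: np.ndarray,
                     bins: int = 256) -> np.ndarray:
    """Map source values onto the target distribution by CDF/quantile lookup.

    Each source value is sent to the target quantile at its own source-CDF
    position, using ``bins`` quantile knots and linear interpolation.  The
    output keeps the source's arrangement (shape) and value ranks and lies
    within ``[min(target), max(target)]``.  Ties in the source map to the
    target quantile of their first occurrence (lowest rank).  With
    ``bins >= n`` (tie-free, equal sizes) the mapping coincides with exact
    rank substitution sorted(source)[k] -> sorted(target)[k].
    """
    src = np.asarray(source_values, dtype=np.float64)
    tgt = np.asarray(target_values, dtype=np.float64)
    if src.size == 0 or tgt.size == 0:
        raise ValueError("histogram matching requires non-empty inputs")
    shape = src.shape
    flat = src.ravel()
    qs = np.linspace(0.0, 1.0, int(bins))
    src_knots = np.quantile(flat, qs)
    tgt_knots = np.quantile(tgt.ravel(), qs)
    # keep the first occurrence of duplicated knots so source ties map to the
    # lowest matching quantile; np.unique on a sorted array does exactly that
    uniq_knots, first_idx = np.unique(src_knots, return_index=True)
    pos = np.interp(flat, uniq_knots, qs[first_idx])
    matched = np.interp(pos, qs, tgt_knots)
    return matched.reshape(shape)


def logcosh(a: np.ndarray, b: np.ndarray) -> float:
    """Mean log(cosh(a - b)), numerically stable for large differences.

    Uses |d| + log1p(e^(-2|d|)) - log 2, which never overflows; behaves like
    half the squared error near zero and like |d| - log 2 in the tails.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    d = np.abs(a - b)
    return float((d + np.log1p(np.exp(-2.0 * d)) - np.log(2.0)).mean())


def _layer_term(a: Tensor, b_data: np.ndarray, bins: int, pooling: str) -> Tensor:
    if pooling == "per_layer_pooled" or a.data.ndim <= 2:
        matched = match_histograms(a.data, b_data, bins=bins)
        return logcosh_to_const(a, matched.astype(np.float64))
    # per-channel: activations (N, C, H, W) matched channel by channel
    matched = np.empty(a.data.shape, dtype=np.float64)
    for c in range(a.data.shape[1]):
        matched[:, c] = match_histograms(a.data[:, c], b_data[:, c], bins=bins)
    return logcosh_to_const(a, matched)


def histogram_loss(source_acts: dict[str, Tensor], target_acts: dict[str, Tensor],
                   config: HistAlignConfig) -> tuple[Tensor, dict[str, float]]:
    """Eq.-style histogram loss summed over tapped layers.

    ``source_acts``/``target_acts`` map tap-layer names to activation Tensors
    captured from a source and a target batch.  The target side enters only
    through the stored matched matrices, so no gradient reaches the target
    forward pass.  Returns the differentiable total and the per-layer values.
    """
    if list(source_acts.keys()) != list(target_acts.keys()):
        raise ValueError(
            f"tap-layer inventories differ: {list(source_acts)} vs {list(target_acts)}"
        )
    if not source_acts:
        raise ValueError("no tapped layers to align")
    terms = []
    per_layer: dict[str, float] = {}
    for name, a in source_acts.items():
        b = target_acts[name]
        term = _layer_term(a, np.asarray(b.data), config.bins, config.pooling)
        per_layer[name] = term.item()
        terms.append(term)
    return scalar_sum(terms), per_layer


def total_loss(ce: float, hist: float, lambda_weight: float) -> float:
    """Joint objective value: cross-entropy plus weighted histogram loss."""
    if not (np.isfinite(ce) and np.isfinite(hist) and np.isfinite(lambda_weight)):
        raise ValueError("loss terms must be finite")
    return float(ce) + float(lambda_weight) * float(hist)
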
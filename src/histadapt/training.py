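"""Supervised training, the two-stage lesion cascade, and transductive
domain adaptation.

Initial training minimises categorical cross-entropy with Adam (batches of
128, up to 200 epochs, learning rate 1e-2) and stops early when validation
accuracy has not improved for 20 consecutive epochs, restoring the best
weights.  Adaptation continues from a pre-trained network at a reduced
learning rate (1e-4): each step draws one labelled source batch and one
unlabelled target batch (both of the histogram match size, 32), and descends
``L_total = L_ce + lambda * L_hist``.  Target labels are unreachable by
construction — target cases enter only through their volume and priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .histalign import HistAlignConfig, LossBreakdown, histogram_loss
from .inference import segment_volume
from .network import Network, NetworkSpec, build_network
from .phantoms import DomainCase
from .sampling import (assemble_arrays, sample_lesions_stage1,
                       sample_lesions_stage2, sample_structures)
from .volumes import LabelMap, PriorAtlas, Volume, normalize_intensity

__all__ = ["TrainConfig", "TrainState", "TrainingSet", "build_training_set",
           "train_initial", "train_cascaded", "adapt_transductive"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 20
    learning_rate: float = 1e-2
    adapt_learning_rate: float = 1e-4
    val_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.learning_rate <= 0 or self.adapt_learning_rate <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class TrainState:
    epoch: int = 0
    best_epoch: int = 0
    best_val_accuracy: float = 0.0
    epochs_since_best: int = 0
    history: list[dict] = field(default_factory=list)


@dataclass
class TrainingSet:
    """Pre-extracted patch arrays for one case: the unit the trainers consume."""

    patches: np.ndarray   # (n, 3, S, S)
    priors: np.ndarray    # (n, K)
    labels: np.ndarray | None  # (n,) int, None for unlabelled target sets

    def __len__(self) -> int:
        return len(self.patches)


def _subsample(voxels: np.ndarray, labels: np.ndarray, cap: int | None,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Cap the sample count, dropping (majority) background samples first.

    Positive samples are kept in full whenever they fit the budget, so a cap
    never destroys the foreground/background balance the samplers set up.
    """
    if cap is None or len(voxels) <= cap:
        return voxels, labels
    pos = np.flatnonzero(labels > 0)
    neg = np.flatnonzero(labels == 0)
    if len(pos) >= cap:
        keep = np.sort(rng.choice(pos, size=cap, replace=False))
    else:
        n_neg = cap - len(pos)
        keep = np.sort(np.concatenate([pos, rng.choice(neg, size=n_neg, replace=False)]))
    return voxels[keep], labels[keep]


def build_training_set(volume: Volume, labels: LabelMap | None, priors: PriorAtlas,
                       task: str, patch_size: int, boundary_margin: int = 5,
                       stage1_prediction: LabelMap | None = None,
                       brain_mask: np.ndarray | None = None,
                       max_samples: int | None = None, seed: int = 0,
                       normalized: bool = False) -> TrainingSet:
    """Sample voxels with the task's strategy and extract their patch arrays.

    For labelled cases the structure strategy takes all structure voxels plus
    boundary negatives; the lesion strategy is balanced stage-1 or stage-2
    sampling (pass ``stage1_prediction`` for stage 2).  For unlabelled target
    cases (``labels=None``) the same strategies run on the atlas argmax, which
    fixes *where* patches are drawn — the resulting set carries no labels.
    """
    rng = np.random.default_rng(seed)
    vol = volume if normalized else normalize_intensity(volume)
    geometry = labels
    if geometry is None:
        pseudo = priors.data.argmax(axis=-1).astype(np.int32)
        if task == "lesions":
            # tissue atlas has no lesion channel: draw target patches from the
            # white-matter region, where lesions occur
            pseudo = (priors.data[..., 0] >= 0.5).astype(np.int32)
        geometry = LabelMap(pseudo, class_count=max(int(pseudo.max()) + 1, 2),
                            spacing=volume.spacing)
    if brain_mask is None:
        brain_mask = volume.data != 0

    if task == "structures":
        positives, negatives = sample_structures(geometry, margin=boundary_margin)
        vox_list = [negatives] + list(positives.values())
        lab_list = [np.zeros(len(negatives), dtype=np.int64)] + [
            np.full(len(v), c, dtype=np.int64) for c, v in positives.items()
        ]
        voxels = np.concatenate(vox_list, axis=0)
        labs = np.concatenate(lab_list, axis=0)
    elif task == "lesions":
        if stage1_prediction is None:
            pos, neg = sample_lesions_stage1(geometry, brain_mask,
                                             seed=int(rng.integers(2**31 - 1)))
        else:
            pos, neg = sample_lesions_stage2(geometry, stage1_prediction, brain_mask,
                                             seed=int(rng.integers(2**31 - 1)))
        voxels = np.concatenate([pos, neg], axis=0)
        labs = np.concatenate([np.ones(len(pos), dtype=np.int64),
                               np.zeros(len(neg), dtype=np.int64)])
    else:
        raise ValueError(f"unknown task {task!r}")

    voxels, labs = _subsample(voxels, labs, max_samples, rng)
    patches, prior_vecs, labs = assemble_arrays(vol, priors, voxels, labs, patch_size)
    return TrainingSet(patches=patches, priors=prior_vecs,
                       labels=None if labels is None else labs)


def _accuracy(network: Network, ts: TrainingSet, idx: np.ndarray) -> float:
    probs = network.predict_proba(ts.patches[idx], ts.priors[idx])
    return float((probs.argmax(axis=1) == ts.labels[idx]).mean())


def _split_indices(n: int, val_fraction: float, rng: np.random.Generator):
    order = rng.permutation(n)
    n_val = min(max(int(round(val_fraction * n)), 1), n - 1)
    return order[n_val:], np.sort(order[:n_val])


def train_initial(network: Network, train_set: TrainingSet,
                  config: TrainConfig) -> tuple[Network, TrainState]:
    """Supervised cross-entropy training with early stopping on validation
    accuracy; the best-validation weights are restored on stop."""
    if train_set.labels is None:
        raise ValueError("initial training requires labelled samples")
    n = len(train_set)
    if n < 4:
        raise ValueError("too few samples to train")
    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = _split_indices(n, config.val_fraction, rng)
    opt = ad.Adam(network.parameters(), lr=config.learning_rate)
    state = TrainState()
    best_weights = network.state_dict()

    for epoch in range(config.max_epochs):
        order = train_idx[rng.permutation(len(train_idx))]
        losses = []
        for i in range(0, len(order), config.batch_size):
            batch = order[i:i + config.batch_size]
            logits, _ = network.forward(train_set.patches[batch], train_set.priors[batch])
            loss = ad.softmax_cross_entropy(logits, train_set.labels[batch])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_acc = _accuracy(network, train_set, val_idx)
        state.epoch = epoch + 1
        state.history.append({"epoch": epoch + 1,
                              "train_loss": float(np.mean(losses)),
                              "val_accuracy": val_acc})
        # stopping counts epochs without an accuracy *increase*; the restored
        # weights track ties to the latest epoch, so a plateau keeps the most
        # trained snapshot instead of the first one that reached it
        if val_acc >= state.best_val_accuracy:
            if val_acc > state.best_val_accuracy:
                state.epochs_since_best = 0
                state.best_epoch = epoch + 1
                state.best_val_accuracy = val_acc
            else:
                state.epochs_since_best += 1
            best_weights = network.state_dict()
        else:
            state.epochs_since_best += 1
        if state.epochs_since_best >= config.patience:
            break
    network.load_state_dict(best_weights)
    return network, state


def train_cascaded(spec: NetworkSpec, volume: Volume, labels: LabelMap,
                   priors: PriorAtlas, config: TrainConfig,
                   max_samples: int | None = None,
                   threshold: float = 0.5) -> tuple[Network, Network, TrainState]:
    """Two-stage lesion training with false-positive-reduction stage 2.

    Stage 1 trains on all lesion voxels vs. equally many random brain voxels;
    its (unfiltered) segmentation of the same training image supplies the
    false positives from which stage 2 draws its negatives.  The stage-2
    network is the deliverable.
    """
    norm = normalize_intensity(volume)
    set1 = build_training_set(norm, labels, priors, task="lesions",
                              patch_size=spec.patch_size, max_samples=max_samples,
                              seed=config.seed, normalized=True)
    net1 = build_network(spec, seed=config.seed)
    net1, _ = train_initial(net1, set1, config)

    pred = segment_volume(net1, norm, priors, mode="lesions", threshold=threshold,
                          postprocess=False)
    if not (pred.labels.data > 0).any():
        raise RuntimeError(
            "cascade error: stage-1 network predicts no lesion voxels on its "
            "own training image; inspect stage-1 training history")
    set2 = build_training_set(norm, labels, priors, task="lesions",
                              patch_size=spec.patch_size,
                              stage1_prediction=pred.labels,
                              max_samples=max_samples, seed=config.seed + 1,
                              normalized=True)
    net2 = build_network(spec, seed=config.seed + 1)
    net2, state2 = train_initial(net2, set2, config)
    return net1, net2, state2


def adapt_transductive(network: Network, source_case: DomainCase,
                       target_case: DomainCase, align: HistAlignConfig,
                       config: TrainConfig, task: str = "structures",
                       boundary_margin: int = 5,
                       max_samples: int | None = None,
                       average_tail: int = 0,
                       select: str = "val_accuracy") -> tuple[Network, TrainState, list[LossBreakdown]]:
    """Adapt a pre-trained network to an unlabelled target case.

    One labelled source case and one unlabelled target case suffice.  Every
    step forwards a source batch and a target batch of ``align.match_batch``
    samples with activation capture, matches the source activation histograms
    to the target's per tapped layer, and descends
    ``L_ce(source) + lambda * L_hist`` at the reduced learning rate.  Early
    stopping monitors held-out *source* validation accuracy (target labels do
    not exist here); best weights are restored.

    Snapshot selection (``select``):

    * ``"val_accuracy"`` — classic early stopping, restore the best
      source-validation-accuracy epoch;
    * ``"hist_loss"`` — restore the epoch with the lowest epoch-mean
      histogram loss among epochs whose source validation accuracy stayed
      within 0.02 of the starting accuracy.  The histogram loss is the
      alignment objective itself and needs no target labels, so when the
      domains already match (the loss starts at its floor) an early snapshot
      is kept and the network barely moves, while under a genuine shift the
      loss keeps falling and a later, better-aligned snapshot is kept.

    With ``average_tail = k > 0`` the returned weights are the element-wise
    average of the last ``k`` per-epoch snapshots (stochastic weight
    averaging), damping the epoch-to-epoch oscillation that batch-level
    histogram matching induces.  ``average_tail`` and ``select="hist_loss"``
    are mutually exclusive.
    """
    if select not in ("val_accuracy", "hist_loss"):
        raise ValueError(f"unknown snapshot selection {select!r}")
    if average_tail > 0 and select == "hist_loss":
        raise ValueError("choose either tail averaging or hist-loss selection")
    if target_case.labels is not None:
        raise ValueError("target case must not expose labels during adaptation")
    if network.spec.prior_units != source_case.priors.n_classes:
        raise ValueError("network prior units do not match the source atlas")
    src = build_training_set(source_case.volume, source_case.labels, source_case.priors,
                             task=task, patch_size=network.spec.patch_size,
                             boundary_margin=boundary_margin,
                             max_samples=max_samples, seed=config.seed)
    tgt = build_training_set(target_case.volume, None, target_case.priors,
                             task=task, patch_size=network.spec.patch_size,
                             boundary_margin=boundary_margin,
                             max_samples=max_samples, seed=config.seed + 1)

    batch = align.match_batch
    rng = np.random.default_rng(config.seed)
    tgt_rng = np.random.default_rng(config.seed + 7919)
    train_idx, val_idx = _split_indices(len(src), config.val_fraction, rng)
    opt = ad.Adam(network.parameters(), lr=config.adapt_learning_rate)
    state = TrainState()
    best_weights = network.state_dict()
    log: list[LossBreakdown] = []
    tail: list[dict[str, np.ndarray]] = []
    start_val_acc = _accuracy(network, src, val_idx)
    hist_candidates: list[tuple[float, dict[str, np.ndarray]]] = []

    use_hist = align.lambda_weight > 0
    for epoch in range(config.max_epochs):
        epoch_hist: list[float] = []
        order = train_idx[rng.permutation(len(train_idx))]
        for i in range(0, len(order) - batch + 1, batch):
            sb = order[i:i + batch]
            tb = tgt_rng.choice(len(tgt), size=batch, replace=len(tgt) < batch)
            logits, src_acts = network.forward(src.patches[sb], src.priors[sb],
                                               capture=use_hist)
            ce = ad.softmax_cross_entropy(logits, src.labels[sb])
            if use_hist:
                _, tgt_acts = network.forward(tgt.patches[tb], tgt.priors[tb],
                                              capture=True)
                hist, per_layer = histogram_loss(src_acts, tgt_acts, align)
                total = ce + align.lambda_weight * hist
                epoch_hist.append(hist.item())
                log.append(LossBreakdown(ce=ce.item(), hist=hist.item(),
                                         lambda_weight=align.lambda_weight,
                                         total=total.item(), per_layer_hist=per_layer))
            else:
                total = ce
                log.append(LossBreakdown(ce=ce.item(), hist=0.0,
                                         lambda_weight=align.lambda_weight,
                                         total=ce.item()))
            opt.zero_grad()
            total.backward()
            opt.step()
        val_acc = _accuracy(network, src, val_idx)
        state.epoch = epoch + 1
        state.history.append({"epoch": epoch + 1, "val_accuracy": val_acc})
        if average_tail > 0:
            tail.append(network.state_dict())
            tail = tail[-average_tail:]
        if select == "hist_loss" and epoch_hist and val_acc >= start_val_acc - 0.02:
            hist_candidates.append((float(np.mean(epoch_hist)), network.state_dict()))
        # same plateau handling as initial training (ties keep the latest)
        if val_acc >= state.best_val_accuracy:
            if val_acc > state.best_val_accuracy:
                state.epochs_since_best = 0
                state.best_epoch = epoch + 1
                state.best_val_accuracy = val_acc
            else:
                state.epochs_since_best += 1
            best_weights = network.state_dict()
        else:
            state.epochs_since_best += 1
        if state.epochs_since_best >= config.patience:
            break
    if select == "hist_loss" and hist_candidates:
        network.load_state_dict(min(hist_candidates, key=lambda c: c[0])[1])
    elif tail:
        averaged = {k: np.mean([w[k] for w in tail], axis=0).astype(tail[0][k].dtype)
                    for k in tail[0]}
        network.load_state_dict(averaged)
    else:
        network.load_state_dict(best_weights)
    return network, state, log
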
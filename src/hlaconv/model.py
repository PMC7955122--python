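"""Multitask convolutional imputation model for classical HLA alleles.

One model is trained per gene *group* (neighbouring genes in strong LD) and
per digit resolution.  The network takes the one-hot encoding of each phased
haplotype's SNVs inside the group window and pushes it through a shared trunk
(two convolution + batch-norm + max-pool blocks and a fully-connected layer)
into per-gene softmax heads, one output unit per classical allele, so each
head emits a per-haplotype allele probability vector summing to 1.

Training minimises the per-gene categorical cross-entropy with Adam; the
per-task losses are balanced each step with MGDA-UB weights computed from the
task gradients at the shared representation.  5% of the samples are held out
as a sub-validation set that controls nothing but the early-stopping epoch; the
parameter snapshot at the best sub-validation loss is restored.  Hierarchical
fine-tuning trains 2-digit first and initialises each finer resolution's
shared trunk from the coarser model.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .panel import UNKNOWN, GeneGroup, PhasedPanel, encode_window
from .simulate import _rng as _substream

RESOLUTIONS = (2, 4, 6)

# Approximate GRCh37 gene start coordinates on chromosome 6 (configurable via
# the ``coords`` argument of :func:`default_groups`).
DEFAULT_GENE_POS: dict[str, int] = {
    "F": 29_691_117, "V": 29_758_731, "G": 29_794_744, "H": 29_855_350,
    "K": 29_926_659, "A": 29_910_247, "J": 29_974_360, "L": 30_227_361,
    "E": 30_457_183,
    "C": 31_236_526, "B": 31_321_649, "MICA": 31_367_561, "MICB": 31_462_658,
    "DRA": 32_407_619, "DRB9": 32_427_598, "DRB5": 32_485_120,
    "DRB4": 32_491_000, "DRB3": 32_452_000, "DRB8": 32_455_000,
    "DRB7": 32_442_500, "DRB6": 32_520_000, "DRB2": 32_590_000,
    "DRB1": 32_546_547, "DQA1": 32_605_183, "DOB": 32_780_540,
    "DQB1": 32_627_244,
    "TAP2": 32_789_610, "TAP1": 32_812_986, "DMB": 32_902_406,
    "DMA": 32_916_390, "DOA": 32_971_955, "DPA1": 33_032_346,
    "DPB1": 33_043_703,
}

# The four LD-based gene sets used for grouping on real panels.
DEFAULT_GROUP_GENES: list[list[str]] = [
    ["F", "V", "G", "H", "K", "A", "J", "L", "E"],
    ["C", "B", "MICA", "MICB"],
    ["DRA", "DRB9", "DRB5", "DRB4", "DRB3", "DRB8", "DRB7", "DRB6", "DRB2",
     "DRB1", "DQA1", "DOB", "DQB1"],
    ["TAP2", "TAP1", "DMB", "DMA", "DOA", "DPA1", "DPB1"],
]


@dataclass
class ModelHyperparams:
    conv1_filters: int = 128
    conv2_filters: int = 64
    kernel1: int = 7
    kernel2: int = 5
    pool: int = 2
    shared_fc_units: int = 256
    dropout_rate: float = 0.25
    batch_size: int = 64
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 20
    val_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("conv1_filters", "conv2_filters", "kernel1", "kernel2",
                     "pool", "shared_fc_units", "batch_size", "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must be in (0, 0.5)")
        if not 0.0 < self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def default_groups(
    panel: PhasedPanel | None = None,
    coords: dict[str, int] | None = None,
    window_bp: int = 500_000,
) -> list[GeneGroup]:
    """The four LD-based gene groups, restricted to genes imputable from the
    panel (typed with at least two alleles).  Unknown gene names in ``coords``
    overrides raise."""
    coords = dict(DEFAULT_GENE_POS if coords is None else coords)
    groups = []
    for i, genes in enumerate(DEFAULT_GROUP_GENES, 1):
        missing = [g for g in genes if g not in coords]
        if missing:
            raise ValueError(f"no coordinates for genes {missing}")
        if panel is not None:
            genes = [
                g for g in genes
                if g in panel.hla_labels
                and any(len(panel.alleles(g, r)) >= 2 for r in panel.resolutions(g))
            ]
        if genes:
            groups.append(GeneGroup(f"group{i}", genes, coords, window_bp))
    return groups


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------


class MultitaskCNN:
    """Shared conv trunk + per-gene softmax heads over a fixed SNV window."""

    def __init__(self, window: int, head_sizes: dict[str, int], hp: ModelHyperparams,
                 rng: np.random.Generator):
        self.hp = hp
        self.window = window
        L1 = window // hp.pool
        L2 = L1 // hp.pool
        if L2 < 1:
            raise ValueError(f"window of {window} SNVs too small for two pools of {hp.pool}")
        self.flat_features = hp.conv2_filters * L2
        self.shared: list[nn.Layer] = [
            nn.Conv1d(2, hp.conv1_filters, hp.kernel1, rng),
            nn.BatchNorm1d(hp.conv1_filters),
            nn.ReLU(),
            nn.Dropout(hp.dropout_rate),
            nn.MaxPool1d(hp.pool),
            nn.Conv1d(hp.conv1_filters, hp.conv2_filters, hp.kernel2, rng),
            nn.BatchNorm1d(hp.conv2_filters),
            nn.ReLU(),
            nn.Dropout(hp.dropout_rate),
            nn.MaxPool1d(hp.pool),
            nn.Flatten(),
            nn.Linear(self.flat_features, hp.shared_fc_units, rng),
            nn.ReLU(),
            nn.Dropout(hp.dropout_rate),
        ]
        self.heads: dict[str, nn.Linear] = {
            g: nn.Linear(hp.shared_fc_units, k, rng) for g, k in head_sizes.items()
        }

    # -- parameter bookkeeping --------------------------------------------
    @property
    def shared_params(self) -> list[np.ndarray]:
        return [p for layer in self.shared for p in layer.params]

    @property
    def shared_grads(self) -> list[np.ndarray]:
        return [g for layer in self.shared for g in layer.grads]

    def all_params(self) -> list[np.ndarray]:
        return self.shared_params + [p for g in sorted(self.heads) for p in self.heads[g].params]

    def all_grads(self) -> list[np.ndarray]:
        return self.shared_grads + [gr for g in sorted(self.heads) for gr in self.heads[g].grads]

    def _bn_layers(self) -> list[nn.BatchNorm1d]:
        return [l for l in self.shared if isinstance(l, nn.BatchNorm1d)]

    def snapshot(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.all_params()]
        for bn in self._bn_layers():
            state += [bn.running_mean.copy(), bn.running_var.copy()]
        return state

    def restore(self, state: list[np.ndarray]) -> None:
        params = self.all_params()
        for p, s in zip(params, state):
            p[...] = s
        rest = state[len(params):]
        for bn, mean, var in zip(self._bn_layers(), rest[::2], rest[1::2]):
            bn.running_mean[...] = mean
            bn.running_var[...] = var

    def shared_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.shared_params]
        for bn in self._bn_layers():
            state += [bn.running_mean.copy(), bn.running_var.copy()]
        return state

    def load_shared_state(self, state: list[np.ndarray]) -> None:
        params = self.shared_params
        for p, s in zip(params, state):
            p[...] = s
        rest = state[len(params):]
        for bn, mean, var in zip(self._bn_layers(), rest[::2], rest[1::2]):
            bn.running_mean[...] = mean
            bn.running_var[...] = var

    # -- passes ------------------------------------------------------------
    def forward_shared(self, X: np.ndarray, train: bool, rng=None) -> np.ndarray:
        h = X
        for layer in self.shared:
            h = layer.forward(h, train, rng)
        return h

    def forward(self, X: np.ndarray, train: bool = False, rng=None) -> dict[str, np.ndarray]:
        z = self.forward_shared(X, train, rng)
        return {g: head.forward(z, train) for g, head in self.heads.items()}

    def backward_shared(self, dz: np.ndarray) -> np.ndarray:
        for layer in reversed(self.shared):
            dz = layer.backward(dz)
        return dz

    def input_gradient(self, X: np.ndarray, gene: str, allele_idx: int) -> np.ndarray:
        """d(pre-softmax score of one allele)/d(input), inference mode."""
        z = self.forward_shared(X, train=False)
        head = self.heads[gene]
        head.forward(z, train=False)
        dlogits = np.zeros((X.shape[0], head.W.shape[0]))
        dlogits[:, allele_idx] = 1.0
        dz = head.backward(dlogits)
        return self.backward_shared(dz)


@dataclass
class TrainedGroupModel:
    """A trained group/resolution model with its window and allele lists."""

    group: GeneGroup
    resolution: int
    genes: list[str]
    alleles: dict[str, list[str]]
    variant_ids: list[str]
    net: MultitaskCNN
    hp: ModelHyperparams
    log: pd.DataFrame
    stopped_epoch: int


@dataclass
class AlleleProbabilities:
    """Per-haplotype, per-gene probability vectors over classical alleles.

    Haplotypes ``2i`` and ``2i+1`` belong to sample ``sample_ids[i]``.
    """

    sample_ids: list[str]
    probs: dict[str, np.ndarray]  # gene -> (2n, n_alleles)
    alleles: dict[str, list[str]]

    def __post_init__(self):
        n_hap = 2 * len(self.sample_ids)
        for g, p in self.probs.items():
            if p.shape != (n_hap, len(self.alleles[g])):
                raise ValueError(f"{g}: probability matrix shape {p.shape} inconsistent")
            if np.any(p < -1e-9) or np.abs(p.sum(axis=1) - 1.0).max() > 1e-5:
                raise ValueError(f"{g}: probabilities must be in [0,1] and sum to 1")

    @property
    def genes(self) -> list[str]:
        return list(self.probs)

    def merge(self, other: "AlleleProbabilities") -> "AlleleProbabilities":
        if self.sample_ids != other.sample_ids:
            raise ValueError("sample ids differ")
        return AlleleProbabilities(
            self.sample_ids,
            {**self.probs, **other.probs},
            {**self.alleles, **other.alleles},
        )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _group_targets(panel: PhasedPanel, genes: list[str], resolution: int):
    """Per-gene integer targets with label masks; genes with <2 alleles drop."""
    kept, targets, masks, alleles = [], {}, {}, {}
    for g in genes:
        if g not in panel.hla_labels:
            warnings.warn(f"gene {g} untyped in panel; dropped from group")
            continue
        lab = panel.effective_labels(g, resolution)
        names = sorted(a for a in set(lab.tolist()) if a != UNKNOWN)
        if len(names) < 2:
            warnings.warn(f"gene {g} has <2 alleles at {resolution}-digit; dropped")
            continue
        index = {a: i for i, a in enumerate(names)}
        mask = lab != UNKNOWN
        tgt = np.zeros(len(lab), dtype=np.int64)
        tgt[mask] = [index[a] for a in lab[mask]]
        kept.append(g)
        targets[g], masks[g], alleles[g] = tgt, mask, names
    return kept, targets, masks, alleles


def train_group(
    panel: PhasedPanel,
    group: GeneGroup,
    hp: ModelHyperparams,
    resolution: int = 4,
    init: TrainedGroupModel | None = None,
) -> TrainedGroupModel:
    """Train one multitask model; deterministic given ``hp.seed``.

    The sub-validation split is drawn at the *sample* level (both haplotypes
    of an individual stay on the same side) and controls only early stopping;
    the returned parameters are the snapshot with the best sub-validation
    loss.  ``init`` transfers a coarser-resolution model's shared trunk
    (hierarchical fine-tuning).
    """
    genes, targets, masks, alleles = _group_targets(panel, group.genes, resolution)
    if not genes:
        raise ValueError(f"group {group.name}: no trainable gene at {resolution}-digit")
    X, idx = encode_window(panel, group)
    variant_ids = [panel.variants[i].id for i in idx]

    ss = np.random.SeedSequence(hp.seed)
    net = MultitaskCNN(X.shape[2], {g: len(alleles[g]) for g in genes}, hp,
                       _substream(ss, "init"))
    if init is not None:
        if init.variant_ids != variant_ids:
            raise ValueError("init model was trained on a different SNV window")
        net.load_shared_state(init.net.shared_state())

    n = panel.n_samples
    n_val = max(1, int(round(hp.val_fraction * n)))
    perm = _substream(ss, "split").permutation(n)
    val_samples, train_samples = perm[:n_val], perm[n_val:]
    val_hap = np.sort(np.concatenate([[2 * i, 2 * i + 1] for i in val_samples]))
    train_hap = np.concatenate([[2 * i, 2 * i + 1] for i in train_samples])

    opt = nn.Adam(net.all_params(), lr=hp.learning_rate)
    rng_shuffle = _substream(ss, "shuffle")
    rng_drop = _substream(ss, "dropout")

    def eval_loss(hap_rows: np.ndarray) -> float:
        logits = net.forward(X[hap_rows], train=False)
        losses = []
        for g in genes:
            m = masks[g][hap_rows]
            if m.any():
                loss, _ = nn.cross_entropy(logits[g], targets[g][hap_rows], m)
                losses.append(loss)
        return float(np.mean(losses))

    best_val, best_state, best_epoch, wait = np.inf, net.snapshot(), 0, 0
    records = []
    n_shared = len(net.shared_params)
    for epoch in range(hp.max_epochs):
        order = rng_shuffle.permutation(train_hap)
        epoch_train_losses, epoch_weights = [], []
        for start in range(0, len(order), hp.batch_size):
            rows = order[start : start + hp.batch_size]
            z = net.forward_shared(X[rows], train=True, rng=rng_drop)
            dz_tasks, batch_losses = [], []
            head_grads = {}
            for g in genes:
                head = net.heads[g]
                logits = head.forward(z, train=True)
                loss, dlogits = nn.cross_entropy(logits, targets[g][rows], masks[g][rows])
                dz_tasks.append(head.backward(dlogits))
                head_grads[g] = [gr.copy() for gr in head.grads]
                batch_losses.append(loss)
            w = nn.mgda_ub_weights(dz_tasks)
            dz = sum(wt * d for wt, d in zip(w, dz_tasks))
            net.backward_shared(dz)
            # task-specific head parameters keep their own unscaled gradients
            grads = net.shared_grads + [
                gr for g in sorted(net.heads) for gr in head_grads[g]
            ]
            opt.step(grads)
            epoch_train_losses.append(float(np.mean(batch_losses)))
            epoch_weights.append(w)
        val_loss = eval_loss(val_hap)
        records.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_train_losses)),
                "val_loss": val_loss,
                **{
                    f"mgda_w_{g}": float(np.mean([w[i] for w in epoch_weights]))
                    for i, g in enumerate(genes)
                },
            }
        )
        if val_loss < best_val - 1e-9:
            best_val, best_state, best_epoch, wait = val_loss, net.snapshot(), epoch, 0
        else:
            wait += 1
            if wait >= hp.patience:
                break
    net.restore(best_state)
    return TrainedGroupModel(
        group=group,
        resolution=resolution,
        genes=genes,
        alleles=alleles,
        variant_ids=variant_ids,
        net=net,
        hp=hp,
        log=pd.DataFrame(records),
        stopped_epoch=best_epoch,
    )


def hierarchical_train(
    panel: PhasedPanel,
    group: GeneGroup,
    hp: ModelHyperparams,
    resolutions: list[int] | None = None,
) -> dict[int, TrainedGroupModel]:
    """Train coarse-to-fine, transferring the shared trunk at each step."""
    if resolutions is None:
        typed = {
            r for g in group.genes if g in panel.hla_labels for r in panel.resolutions(g)
        }
        resolutions = sorted(typed)
    if not resolutions:
        raise ValueError("panel carries no typed resolution for this group")
    out: dict[int, TrainedGroupModel] = {}
    prev = None
    for res in sorted(resolutions):
        out[res] = train_group(panel, group, hp, resolution=res, init=prev)
        prev = out[res]
    return out


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def _align_target(model: TrainedGroupModel, target: PhasedPanel,
                  missing_mode: str, missing_threshold: float):
    """One-hot window for a target panel aligned to the model's variants.

    Model variants absent from the target are filled with the reference
    one-hot (logged warning) unless ``missing_mode == "error"``.
    """
    col = {v.id: j for j, v in enumerate(target.variants)}
    W = len(model.variant_ids)
    X = np.zeros((target.n_haplotypes, 2, W))
    missing = [vid for vid in model.variant_ids if vid not in col]
    if len(missing) > missing_threshold * W:
        raise ValueError(
            f"{len(missing)}/{W} model variants absent from target "
            f"(threshold {missing_threshold:.0%})"
        )
    if missing:
        if missing_mode == "error":
            raise ValueError(f"target lacks model variants: {missing[:5]}...")
        warnings.warn(
            f"{len(missing)} model variants absent from target; reference-filled"
        )
    for j, vid in enumerate(model.variant_ids):
        if vid in col:
            alt = target.haplotypes[:, col[vid]]
            X[:, 0, j] = alt == 0
            X[:, 1, j] = alt == 1
        else:
            X[:, 0, j] = 1.0
    return X


def impute(
    model: TrainedGroupModel,
    target: PhasedPanel | np.ndarray,
    sample_ids: list[str] | None = None,
    missing_mode: str = "fill_ref",
    missing_threshold: float = 0.5,
) -> AlleleProbabilities:
    """Per-haplotype allele probabilities for pre-phased target SNV data."""
    if isinstance(target, PhasedPanel):
        X = _align_target(model, target, missing_mode, missing_threshold)
        sample_ids = list(target.sample_ids)
    else:
        X = np.asarray(target, dtype=float)
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(X.shape[0] // 2)]
    logits = model.net.forward(X, train=False)
    return AlleleProbabilities(
        sample_ids,
        {g: nn.softmax(logits[g]) for g in model.genes},
        {g: list(model.alleles[g]) for g in model.genes},
    )


def mc_dropout_sample(
    model: TrainedGroupModel,
    X_individual: np.ndarray,
    T: int = 200,
    seed: int = 0,
) -> dict[str, list[tuple[str, str]]]:
    """T stochastic diploid best-guess genotypes for one individual.

    Dropout stays active at prediction (fresh masks per call) while batch
    normalisation uses inference statistics.  Genotypes are unordered allele
    pairs; the whole sample set is reproducible from ``seed``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if X_individual.shape[0] != 2:
        raise ValueError("expected the two haplotypes of one individual")
    rng = np.random.default_rng(seed)
    X_rep = np.tile(X_individual, (T, 1, 1))
    logits = model.net.forward(X_rep, train=False, rng=rng)
    out: dict[str, list[tuple[str, str]]] = {}
    for g in model.genes:
        arg = logits[g].argmax(axis=1)
        names = model.alleles[g]
        out[g] = [
            tuple(sorted((names[arg[2 * t]], names[arg[2 * t + 1]])))
            for t in range(T)
        ]
    return out


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: TrainedGroupModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    state = model.net.snapshot()
    np.savez(path / "params.npz", **{f"p{i}": a for i, a in enumerate(state)})
    manifest = {
        "resolution": model.resolution,
        "genes": model.genes,
        "alleles": model.alleles,
        "variant_ids": model.variant_ids,
        "group": {
            "name": model.group.name,
            "genes": model.group.genes,
            "gene_pos": model.group.gene_pos,
            "window_bp": model.group.window_bp,
        },
        "hyperparams": model.hp.__dict__,
        "stopped_epoch": model.stopped_epoch,
        "window": model.net.window,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    model.log.to_csv(path / "training_log.tsv", sep="\t", index=False)


def load_model(path: str | Path) -> TrainedGroupModel:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    hp = ModelHyperparams(**manifest["hyperparams"])
    group = GeneGroup(**manifest["group"])
    net = MultitaskCNN(
        manifest["window"],
        {g: len(a) for g, a in manifest["alleles"].items()},
        hp,
        np.random.default_rng(0),
    )
    data = np.load(path / "params.npz")
    net.restore([data[f"p{i}"] for i in range(len(data.files))])
    return TrainedGroupModel(
        group=group,
        resolution=manifest["resolution"],
        genes=manifest["genes"],
        alleles=manifest["alleles"],
        variant_ids=manifest["variant_ids"],
        net=net,
        hp=hp,
        log=pd.read_csv(path / "training_log.tsv", sep="\t"),
        stopped_epoch=manifest["stopped_epoch"],
    )
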